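"""Ground-truth corneal phantoms for validating the imaging pipeline.

The mouse cornea is modelled as a stack of five optical interfaces
(tear-film/epithelium surface, epithelium/Bowman's, Bowman's/stroma,
stroma/Descemet's membrane, DM/endothelium) draped over a spherical cap.
Layer thickness fields are smooth Gaussian random fields so that the
downstream segmentation can be scored against exactly known truth.
Descemet's membrane (DM) and stromal thickness statistics default to the
published in vivo group values for wild-type and Fuchs-dystrophy (FECD)
mice at 5 and 16 weeks of age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GroupLabel",
    "GroupParams",
    "GROUP_DEFAULTS",
    "Grid",
    "GuttaeSpec",
    "MotionTrace",
    "CornealPhantom",
    "sample_dm_field",
    "build_phantom",
    "breathing_trace",
]

#: thickness-field floor in µm; fields are clipped here so layer ordering
#: can never invert through random excursions
FIELD_FLOOR_UM = 0.3


class GroupLabel(str, Enum):
    WT_5wk = "WT_5wk"
    FECD_5wk = "FECD_5wk"
    WT_16wk = "WT_16wk"
    FECD_16wk = "FECD_16wk"


@dataclass(frozen=True)
class GroupParams:
    """Per-group DM and stroma thickness statistics (µm).

    The means/SDs are interpreted at two levels by different consumers:
    :func:`build_phantom` uses them as the within-map field statistics of a
    single eye, while :mod:`selfrefocm.thickness_stats` Monte-Carlo helpers
    use them as the between-eye distribution.
    """

    label: GroupLabel
    dm_mean: float
    dm_sd: float
    stroma_mean: float
    stroma_sd: float

    def __post_init__(self) -> None:
        if self.dm_mean <= 0:
            raise ValueError("dm_mean must be > 0")
        if self.dm_sd < 0:
            raise ValueError("dm_sd must be >= 0")
        if self.stroma_mean <= 0:
            raise ValueError("stroma_mean must be > 0")
        if self.stroma_sd < 0:
            raise ValueError("stroma_sd must be >= 0")


#: published in vivo group values (µm): DM mean ± SD, stroma mean ± SD
GROUP_DEFAULTS: dict[GroupLabel, GroupParams] = {
    GroupLabel.WT_5wk: GroupParams(GroupLabel.WT_5wk, 1.85, 0.22, 43.66, 8.96),
    GroupLabel.FECD_5wk: GroupParams(GroupLabel.FECD_5wk, 2.74, 0.12, 40.80, 3.37),
    GroupLabel.WT_16wk: GroupParams(GroupLabel.WT_16wk, 2.21, 0.32, 43.66, 5.25),
    GroupLabel.FECD_16wk: GroupParams(GroupLabel.FECD_16wk, 3.20, 0.20, 61.97, 10.42),
}


@dataclass(frozen=True)
class Grid:
    """Lateral sampling grid: ``nx`` fast-axis and ``ny`` slow-axis (frame)
    positions at ``pitch_um`` spacing. Defaults cover the 500 × 500 µm² FOV
    at 500 × 500 A-scans."""

    nx: int = 500
    ny: int = 500
    pitch_um: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid sizes must be >= 1")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be > 0")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.nx * self.pitch_um, self.ny * self.pitch_um)


@dataclass(frozen=True)
class GuttaeSpec:
    """Focal DM excrescences: radially Gaussian bumps that thicken the DM
    locally, the hallmark FECD lesion."""

    count: int
    amplitude_um: float
    radius_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.amplitude_um < 0:
            raise ValueError("guttae amplitude must be >= 0 (guttae only thicken the DM)")
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame bulk axial offset (µm) from breathing."""

    offsets_um: np.ndarray
    breath_period_s: float
    amplitude_um: float
    frame_period_s: float

    @property
    def n_frames(self) -> int:
        return len(self.offsets_um)


# layer names in anterior -> posterior order; thicknesses in µm
DEFAULT_EPITHELIUM_UM = 40.0
DEFAULT_BOWMAN_UM = 2.0
DEFAULT_ENDOTHELIUM_UM = 4.0

INTERFACE_NAMES = (
    "surface",            # tear film / epithelium
    "epi_bowman",         # epithelium / Bowman's
    "bowman_stroma",      # Bowman's / stroma
    "stroma_dm",          # stroma / Descemet's membrane
    "dm_endothelium",     # DM / endothelium
)

#: amplitude reflectance per interface. The specular surface reflection must
#: dominate (it is the self-reference); among internal interfaces the
#: endothelial band is the strongest, as in the recorded B-scans.
DEFAULT_REFLECTIVITIES = {
    "surface": 0.5,
    "epi_bowman": 0.012,
    "bowman_stroma": 0.02,
    "stroma_dm": 0.025,
    "dm_endothelium": 0.05,
}


@dataclass
class CornealPhantom:
    """Ground-truth layered cornea.

    ``interface_depths[name]`` is the per-(x, y) geometric depth in µm of
    each interface measured from the corneal apex (so the surface map equals
    the spherical sag). Arrays are shaped ``(ny, nx)`` = (frames, lateral).
    """

    grid: Grid
    interface_depths: dict[str, np.ndarray]
    reflectivities: dict[str, float]
    n_tissue: float = 1.387
    curvature_radius_um: float = np.inf
    stroma_scatterers_per_ascan: int = 25
    group: GroupParams | None = None
    seed: int | None = None
    guttae: GuttaeSpec | None = field(default=None)
    #: per-interface reflection-phase maps (rad) from sub-resolution
    #: roughness of the internal tissue interfaces; the saline-smoothed
    #: surface is specular (zero phase). None = all interfaces smooth.
    interface_phases: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        depths = [self.interface_depths[n] for n in INTERFACE_NAMES]
        for a, b in zip(depths, depths[1:]):
            if not np.all(b > a):
                raise ValueError("interface depths must be strictly increasing at every (x, y)")

    @property
    def dm_thickness_um(self) -> np.ndarray:
        """Ground-truth DM thickness field (µm)."""
        return self.interface_depths["dm_endothelium"] - self.interface_depths["stroma_dm"]

    @property
    def stroma_thickness_um(self) -> np.ndarray:
        """Ground-truth stromal thickness field (µm)."""
        return self.interface_depths["stroma_dm"] - self.interface_depths["bowman_stroma"]

    @property
    def surface_sag_um(self) -> np.ndarray:
        return self.interface_depths["surface"]

    def layer_stack_at(self, ix: int, iy: int) -> tuple[np.ndarray, np.ndarray]:
        """(depths µm from apex, amplitude reflectances) at one A-scan."""
        d = np.array([self.interface_depths[n][iy, ix] for n in INTERFACE_NAMES])
        a = np.array([self.reflectivities[n] for n in INTERFACE_NAMES])
        return d, a


def _smooth_unit_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field with unit marginal variance."""
    white = rng.standard_normal(shape)
    if sigma_px <= 0:
        return white
    smooth = gaussian_filter(white, sigma_px, mode="wrap")
    # renormalise: smoothing shrinks the variance by the kernel's L2 norm
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma_px, mode="wrap")
    norm = np.sqrt(np.sum(kernel**2))
    return smooth / norm


def sample_dm_field(
    mean_um: float,
    sd_um: float,
    correlation_length_um: float,
    grid: Grid,
    seed: int,
) -> np.ndarray:
    """Sample a smooth positive thickness field of shape ``(ny, nx)``.

    The field is a stationary Gaussian random field smoothed to
    ``correlation_length_um`` (Gaussian kernel sigma), standardised per
    realization so the sample mean and SD equal the request exactly (up to
    the 0.3 µm positivity floor): with long correlation lengths few
    independent patches fit in a map, so an unconditioned draw would let
    the map mean wander by a large fraction of the SD.
    """
    if mean_um <= 0:
        raise ValueError("mean thickness must be > 0")
    if sd_um < 0:
        raise ValueError("sd must be >= 0")
    if sd_um == 0:
        return np.full((grid.ny, grid.nx), float(mean_um))
    rng = np.random.default_rng(seed)
    sigma_px = correlation_length_um / grid.pitch_um
    unit = _smooth_unit_field((grid.ny, grid.nx), sigma_px, rng)
    std = unit.std()
    if std == 0:  # degenerate single-pixel grid
        unit = np.zeros_like(unit)
    else:
        unit = (unit - unit.mean()) / std
    return np.maximum(mean_um + sd_um * unit, FIELD_FLOOR_UM)


def _spherical_sag(grid: Grid, radius_um: float) -> np.ndarray:
    """Sag of a spherical cap over the FOV, zero at the apex (FOV centre)."""
    if not np.isfinite(radius_um):
        return np.zeros((grid.ny, grid.nx))
    if radius_um <= 0:
        raise ValueError("curvature radius must be > 0 (or infinite for flat)")
    x = (np.arange(grid.nx) - (grid.nx - 1) / 2) * grid.pitch_um
    y = (np.arange(grid.ny) - (grid.ny - 1) / 2) * grid.pitch_um
    r2 = x[None, :] ** 2 + y[:, None] ** 2
    if np.any(r2 >= radius_um**2):
        raise ValueError("FOV exceeds the hemisphere of the given curvature radius")
    return radius_um - np.sqrt(radius_um**2 - r2)


def _guttae_bumps(spec: GuttaeSpec, grid: Grid) -> np.ndarray:
    """Sum of radially Gaussian bumps (µm of added DM thickness)."""
    rng = np.random.default_rng(spec.seed)
    bumps = np.zeros((grid.ny, grid.nx))
    x = np.arange(grid.nx) * grid.pitch_um
    y = np.arange(grid.ny) * grid.pitch_um
    for _ in range(spec.count):
        cx = rng.uniform(0, grid.extent_um[0])
        cy = rng.uniform(0, grid.extent_um[1])
        r2 = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
        bumps += spec.amplitude_um * np.exp(-r2 / (2 * (spec.radius_um / 2.355) ** 2))
    return bumps


def build_phantom(
    group: GroupParams | GroupLabel | str,
    grid: Grid = Grid(),
    curvature_radius_um: float = 1400.0,
    guttae: GuttaeSpec | None = None,
    seed: int = 0,
    *,
    correlation_length_um: float = 50.0,
    epithelium_um: float = DEFAULT_EPITHELIUM_UM,
    bowman_um: float = DEFAULT_BOWMAN_UM,
    endothelium_um: float = DEFAULT_ENDOTHELIUM_UM,
    n_tissue: float = 1.387,
    reflectivities: dict[str, float] | None = None,
    rough_interfaces: bool = True,
    phase_correlation_um: float = 10.0,
    stroma_map_sd_um: float | None = None,
) -> CornealPhantom:
    """Build a layered corneal phantom with known ground truth.

    ``group`` supplies the DM and stromal thickness field statistics; the
    epithelium, Bowman's layer and endothelium take fixed plausible
    thicknesses (total cornea ≈ 100 µm). The curvature defaults to the
    ~1.4 mm radius of the mouse cornea; pass ``numpy.inf`` for a flat
    phantom in controlled tests.

    ``rough_interfaces`` draws an independent reflection phase per internal
    interface per (x, y) — tissue interfaces are rough at the sub-wavelength
    scale, so adjacent layer echoes interfere with random rather than fixed
    relative phase. The specular surface keeps zero phase. Disable for a
    fully coherent mirror-like phantom.
    """
    if isinstance(group, str) and not isinstance(group, GroupLabel):
        group = GroupLabel(group)
    if isinstance(group, GroupLabel):
        group = GROUP_DEFAULTS[group]

    rng = np.random.default_rng(seed)
    stroma_seed, dm_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    if stroma_map_sd_um is None:
        # the group-level stromal SD is dominated by between-animal spread;
        # within one aligned central FOV the stroma varies by a couple of
        # microns at most
        stroma_map_sd_um = min(group.stroma_sd, 2.0)
    stroma = sample_dm_field(group.stroma_mean, stroma_map_sd_um, correlation_length_um, grid, stroma_seed)
    dm = sample_dm_field(group.dm_mean, group.dm_sd, correlation_length_um, grid, dm_seed)
    if guttae is not None and guttae.count > 0:
        dm = dm + _guttae_bumps(guttae, grid)

    phases = None
    if rough_interfaces:
        # laterally correlated phase fields: roughness decorrelates over
        # ~10 µm — longer than the 5-frame averaging span, so frames inside
        # one window see nearly the same phase, while distant patches of the
        # map explore the full circle
        sigma_px = phase_correlation_um / grid.pitch_um
        phases = {}
        for name in INTERFACE_NAMES[1:]:
            re = _smooth_unit_field((grid.ny, grid.nx), sigma_px, rng)
            im = _smooth_unit_field((grid.ny, grid.nx), sigma_px, rng)
            phases[name] = np.arctan2(im, re) + np.pi

    sag = _spherical_sag(grid, curvature_radius_um)
    depths = {"surface": sag}
    depths["epi_bowman"] = depths["surface"] + epithelium_um
    depths["bowman_stroma"] = depths["epi_bowman"] + bowman_um
    depths["stroma_dm"] = depths["bowman_stroma"] + stroma
    depths["dm_endothelium"] = depths["stroma_dm"] + dm

    return CornealPhantom(
        grid=grid,
        interface_depths=depths,
        reflectivities=dict(reflectivities or DEFAULT_REFLECTIVITIES),
        n_tissue=n_tissue,
        curvature_radius_um=curvature_radius_um,
        group=group,
        seed=seed,
        guttae=guttae,
        interface_phases=phases,
    )


def breathing_trace(
    n_frames: int,
    frame_period_s: float,
    breath_period_s: float = 1.5,
    amplitude_um: float = 5.0,
    seed: int = 0,
    jitter_um: float = 0.0,
) -> MotionTrace:
    """Breathing-induced bulk axial motion, one offset per frame.

    A sinusoid at the breathing period (1–2 s under anesthesia) with a
    seed-dependent phase, plus optional white jitter. The trace is
    mean-centred — only relative axial position is physical — and clipped
    to ±amplitude.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if breath_period_s <= 0:
        raise ValueError("breath_period must be > 0")
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_period_s
    phase = rng.uniform(0, 2 * np.pi)
    offsets = amplitude_um * np.sin(2 * np.pi * t / breath_period_s + phase)
    if jitter_um > 0:
        offsets = offsets + jitter_um * rng.standard_normal(n_frames)
    if amplitude_um == 0 and jitter_um == 0:
        offsets = np.zeros(n_frames)
    else:
        # exact zero mean; renormalise so the excursion never exceeds the
        # requested amplitude even when the record holds < 1 breath period
        offsets = offsets - offsets.mean()
        peak = np.max(np.abs(offsets))
        if peak > 0:
            offsets = offsets * min(1.0, (amplitude_um + jitter_um) / peak)
    return MotionTrace(
        offsets_um=offsets,
        breath_period_s=breath_period_s,
        amplitude_um=amplitude_um,
        frame_period_s=frame_period_s,
    )
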