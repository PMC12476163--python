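"""Volume, phantom and result I/O plus run configuration.

HDF5 is the authoritative container (arrays + ground truth + metadata);
multi-page TIFF is provided for viewer interoperability (a TIFF carries no
ground truth and must declare or be given the depth-pixel pitch).
Thickness maps are written as CSV (NaN as empty cells) and 32-bit float
TIFF; summaries as JSON with full provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .dm_segmentation import PipelineParams, SegmentationGates, ThicknessMap, summarize_map
from .ocm_forward import AxialCalibration, OCMVolume
from .synthetic_cornea import CornealPhantom, Grid, GuttaeSpec

__all__ = [
    "RunConfig",
    "load_volume",
    "save_volume",
    "save_raw_volume",
    "load_raw_volume",
    "save_phantom",
    "load_phantom",
    "save_outputs",
]


@dataclass
class RunConfig:
    """Structured pipeline configuration; round-trips through YAML."""

    simulation: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            simulation=data.get("simulation", {}),
            segmentation=data.get("segmentation", {}),
            stats=data.get("stats", {}),
            output_dir=data.get("output_dir", "."),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def save_volume(volume: OCMVolume, path: str | Path) -> None:
    """Write a volume; format chosen by extension (.h5/.hdf5 or .tif/.tiff)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("volume", data=volume.data, compression="gzip")
            fh.attrs["mode"] = volume.mode
            fh.attrs["um_per_pixel_tissue"] = volume.calib.um_per_pixel_tissue
            fh.attrs["n_tissue"] = volume.calib.n_tissue
            fh.attrs["fov_um"] = volume.fov_um
            fh.attrs["frame_period_s"] = volume.frame_period_s
            if volume.phantom is not None:
                _write_phantom_group(fh.create_group("ground_truth"), volume.phantom)
            if volume.motion is not None:
                fh.create_dataset("motion_offsets_um", data=volume.motion.offsets_um)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            volume.data.astype(np.float32),
            photometric="minisblack",
            metadata={
                "mode": volume.mode,
                "um_per_pixel_tissue": volume.calib.um_per_pixel_tissue,
                "n_tissue": volume.calib.n_tissue,
            },
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def load_volume(
    path: str | Path,
    um_per_pixel_tissue: float | None = None,
    n_tissue: float | None = None,
) -> OCMVolume:
    """Load a volume from HDF5 or TIFF, frame-major.

    The depth-pixel pitch must come from file metadata or the
    ``um_per_pixel_tissue`` override; a TIFF without either is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            data = fh["volume"][...]
            calib = AxialCalibration(
                um_per_pixel_tissue=um_per_pixel_tissue
                if um_per_pixel_tissue is not None
                else float(fh.attrs["um_per_pixel_tissue"]),
                n_tissue=n_tissue if n_tissue is not None else float(fh.attrs["n_tissue"]),
            )
            mode = str(fh.attrs.get("mode", "selfref"))
            fov = tuple(fh.attrs.get("fov_um", (500.0, 500.0)))
            frame_period = float(fh.attrs.get("frame_period_s", 0.002))
        return OCMVolume(data=data, mode=mode, calib=calib, fov_um=fov,
                         frame_period_s=frame_period)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        pitch = um_per_pixel_tissue if um_per_pixel_tissue is not None else meta.get("um_per_pixel_tissue")
        if pitch is None:
            raise ValueError(
                "TIFF carries no depth-pixel pitch; pass um_per_pixel_tissue (e.g. --calib)"
            )
        nt = n_tissue if n_tissue is not None else meta.get("n_tissue", 1.387)
        calib = AxialCalibration(um_per_pixel_tissue=float(pitch), n_tissue=float(nt))
        if data.ndim == 2:
            data = data[None]
        return OCMVolume(data=np.asarray(data, dtype=float),
                         mode=str(meta.get("mode", "selfref")), calib=calib)
    raise ValueError(f"unsupported volume format: {path.suffix}")


def save_raw_volume(
    raw: np.ndarray,
    path: str | Path,
    mode: str = "selfref",
    background: np.ndarray | None = None,
) -> None:
    """Write a raw interferogram volume (frames × lateral × spectral
    samples) to HDF5, optionally with the recorded background spectrum."""
    raw = np.asarray(raw)
    if raw.ndim != 3:
        raise ValueError("expected (frames, lateral, spectral) raw volume")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("raw", data=raw, compression="gzip")
        fh.attrs["mode"] = mode
        if background is not None:
            fh.create_dataset("background", data=background)


def load_raw_volume(path: str | Path) -> tuple[np.ndarray, str, np.ndarray | None]:
    """Load a raw interferogram volume: (raw, mode, background|None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        raw = fh["raw"][...]
        mode = str(fh.attrs.get("mode", "selfref"))
        background = fh["background"][...] if "background" in fh else None
    return raw, mode, background


def _write_phantom_group(grp: h5py.Group, phantom: CornealPhantom) -> None:
    for name, arr in phantom.interface_depths.items():
        grp.create_dataset(f"interface/{name}", data=arr)
    if phantom.interface_phases is not None:
        for name, arr in phantom.interface_phases.items():
            grp.create_dataset(f"phase/{name}", data=arr)
    grp.attrs["n_tissue"] = phantom.n_tissue
    grp.attrs["curvature_radius_um"] = phantom.curvature_radius_um
    grp.attrs["nx"] = phantom.grid.nx
    grp.attrs["ny"] = phantom.grid.ny
    grp.attrs["pitch_um"] = phantom.grid.pitch_um
    grp.attrs["stroma_scatterers_per_ascan"] = phantom.stroma_scatterers_per_ascan
    if phantom.seed is not None:
        grp.attrs["seed"] = phantom.seed
    if phantom.group is not None:
        grp.attrs["group_label"] = phantom.group.label.value
    if phantom.guttae is not None:
        g = phantom.guttae
        grp.attrs["guttae"] = (g.count, g.amplitude_um, g.radius_um, g.seed)
    for name, r in phantom.reflectivities.items():
        grp.attrs[f"reflectivity/{name}"] = r


def save_phantom(phantom: CornealPhantom, path: str | Path) -> None:
    """Serialize a phantom (ground truth + metadata) to HDF5."""
    with h5py.File(path, "w") as fh:
        _write_phantom_group(fh, phantom)


def load_phantom(path: str | Path) -> CornealPhantom:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        depths = {k: fh[f"interface/{k}"][...] for k in fh["interface"]}
        phases = None
        if "phase" in fh:
            phases = {k: fh[f"phase/{k}"][...] for k in fh["phase"]}
        refl = {
            k.split("/", 1)[1]: float(v)
            for k, v in fh.attrs.items()
            if k.startswith("reflectivity/")
        }
        grid = Grid(int(fh.attrs["nx"]), int(fh.attrs["ny"]), float(fh.attrs["pitch_um"]))
        guttae = None
        if "guttae" in fh.attrs:
            c, a, r, s = fh.attrs["guttae"]
            guttae = GuttaeSpec(int(c), float(a), float(r), int(s))
        return CornealPhantom(
            grid=grid,
            interface_depths=depths,
            reflectivities=refl,
            n_tissue=float(fh.attrs["n_tissue"]),
            curvature_radius_um=float(fh.attrs["curvature_radius_um"]),
            stroma_scatterers_per_ascan=int(fh.attrs.get("stroma_scatterers_per_ascan", 25)),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            guttae=guttae,
            interface_phases=phases,
        )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


def save_outputs(
    tmap: ThicknessMap,
    out_dir: str | Path,
    config: RunConfig | None = None,
    stem: str = "thickness",
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write a thickness map as CSV + float TIFF and a JSON summary.

    CSV encodes NaN as empty cells. The JSON summary records mean/SD/valid
    fraction, the calibration and gate parameters in force, the package
    version, and the config hash when a config is given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}_map.csv"
    tif_path = out_dir / f"{stem}_map.tif"
    json_path = out_dir / f"{stem}_summary.json"

    np.savetxt(csv_path, tmap.values_um, delimiter=",", fmt="%.6f")
    # rewrite nan tokens as empty fields
    text = csv_path.read_text().replace("nan", "")
    csv_path.write_text(text)
    tifffile.imwrite(tif_path, tmap.values_um.astype(np.float32))

    mean, sd, frac = summarize_map(tmap)
    summary = {
        "layer": tmap.layer,
        "mean_um": None if np.isnan(mean) else mean,
        "sd_um": None if np.isnan(sd) else sd,
        "valid_fraction": frac,
        "shape": list(tmap.values_um.shape),
        "um_per_pixel_tissue": tmap.calib.um_per_pixel_tissue,
        "n_tissue": tmap.calib.n_tissue,
        "package_version": __version__,
    }
    if config is not None:
        summary["config_hash"] = config.digest()
    if extra:
        summary.update(extra)
    json_path.write_text(json.dumps(summary, indent=2, default=_json_default))
    return {"csv": csv_path, "tiff": tif_path, "json": json_path}
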