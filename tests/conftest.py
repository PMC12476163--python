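"""Shared fixtures: small phantoms and volumes sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from selfrefocm.ocm_forward import AxialCalibration, NoiseConfig, ScanConfig, simulate_volume
from selfrefocm.synthetic_cornea import GroupLabel, GroupParams, Grid, build_phantom


@pytest.fixture(scope="session")
def calib() -> AxialCalibration:
    return AxialCalibration()


def make_flat_phantom(
    dm_um: float,
    nx: int = 24,
    ny: int = 8,
    seed: int = 3,
    dm_sd: float = 0.02,
    stroma_um: float = 44.0,
    stroma_sd: float = 0.8,
    **kwargs,
):
    """Flat phantom with a near-constant DM field of known mean."""
    gp = GroupParams(GroupLabel.WT_5wk, dm_um, dm_sd, stroma_um, stroma_sd)
    grid = Grid(nx=nx, ny=ny, pitch_um=1.0)
    return build_phantom(gp, grid, curvature_radius_um=np.inf, seed=seed, **kwargs)


def make_volume(phantom, mode="selfref", motion=None, noise=NoiseConfig(), seed=0, **kwargs):
    grid = phantom.grid
    scan = ScanConfig(
        n_ascans=grid.nx,
        n_frames=grid.ny,
        fov_um=(grid.nx * grid.pitch_um, grid.ny * grid.pitch_um),
    )
    return simulate_volume(phantom, scan, motion=motion, mode=mode, noise_cfg=noise,
                           seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_selfref_volume():
    """Noiseless self-referenced volume of a flat 4 µm DM phantom."""
    return make_volume(make_flat_phantom(4.0))
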