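"""Shared fixtures: scaled-down acquisition chains reused across test modules.

The scaled system is a 16+16 RCA at the same 150-um pitch (2.4-mm aperture)
imaging shallower targets; wavelength, pulse and processing are identical to
the full-size sensor, so the physics exercised is the same at a fraction of
the cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from rcflow import (
    ArraySpec,
    Medium,
    PulseSpec,
    VoxelGrid,
    build_scheme,
    make_bead_phantom,
    make_flow_tube,
    simulate_ensemble,
    beamform_series,
)
from rcflow.simulator import add_noise


@pytest.fixture(scope="session")
def small_setup():
    return {
        "array": ArraySpec(n_rows=16, n_cols=16),
        "pulse": PulseSpec(),
        "medium": Medium(),
    }


@pytest.fixture(scope="session")
def small_grid(small_setup):
    lam = small_setup["medium"].wavelength(small_setup["pulse"].f0)
    return VoxelGrid.regular((-1.1e-3, 1.1e-3), (-1.1e-3, 1.1e-3), (1.8e-3, 3.0e-3), (lam / 2, lam / 2, lam / 4))


@pytest.fixture(scope="session")
def bead_small(small_setup, small_grid):
    """Bead at 2.4 mm imaged with OPW8+8 on the 16+16 array."""
    s = small_setup
    scheme = build_scheme("OPW", s["array"], n_angles=8)
    phantom = make_bead_phantom(depth=2.4e-3)
    data = simulate_ensemble(phantom, scheme, s["pulse"], s["medium"], s["array"], depth_max=4.5e-3)
    series = beamform_series(data, small_grid)
    return {"scheme": scheme, "phantom": phantom, "data": data, "series": series}


@pytest.fixture(scope="session")
def tube_run(small_setup):
    """Flow tube (500 um, 1 cm/s, horizontal) imaged for 200 frames with noise.

    The scaled bench fixture behind the Doppler tests: OPW32+32 on the 16+16
    array at 2-mm depth, 10-dB channel SNR, with the ground-truth flow mask.
    """
    s = small_setup
    lam = s["medium"].wavelength(s["pulse"].f0)
    fov = 1.2e-3
    phantom = make_flow_tube(
        diameter=500e-6,
        depth=2.0e-3,
        speed=0.01,
        blood_density=400.0,
        gel_density=20.0,
        seed=7,
        fov_x=(-fov, fov),
        fov_y=(-fov, fov),
        fov_z=(1.2e-3, 2.8e-3),
    )
    scheme = build_scheme("OPW", s["array"], n_angles=32, prf_hz=3e3)
    grid = VoxelGrid.regular((-fov, fov), (-fov, fov), (1.4e-3, 2.6e-3), (lam / 2, lam / 2, lam / 2))
    from rcflow.pipeline import acquire_series

    series = acquire_series(
        phantom, scheme, grid, n_frames=200, pulse=s["pulse"], medium=s["medium"], array=s["array"],
        depth_max=4.0e-3, snr_db=10.0, seed=11,
    )
    mask = phantom.flow_mask(grid)
    return {"phantom": phantom, "scheme": scheme, "series": series, "grid": grid, "flow_mask": mask}
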