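"""Shared fixtures: compact imaging geometry and rendered single-emitter helpers.

Tests run on reduced fields of view (12-16 planes, 48 px lateral) so the
full suite stays fast; the optics, photon budget and noise model are the
package defaults throughout.
"""

from dataclasses import replace

import numpy as np
import pytest

from escrtdyn.geometry import (default_camera, default_egfp, default_geometry,
                               default_psf)
from escrtdyn.synthetic import EmitterTruth, Scene
from escrtdyn.render import render_volume_series


@pytest.fixture(scope="session")
def geom_small():
    return replace(default_geometry(), volume_shape=(16, 48, 48),
                   planes_per_volume=16, n_volumes=20)


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def psf():
    return default_psf()


@pytest.fixture(scope="session")
def egfp():
    return default_egfp()


@pytest.fixture(scope="session")
def voxel_size(geom_small):
    return geom_small.voxel_size()


def single_emitter_series(geom, camera, psf, egfp, n_molecules, n_frames,
                          rng, jitter=True, position_vox=None):
    """Render one immobile emitter; returns (VolumeSeries, positions_nm)."""
    vz, vy, vx = geom.voxel_size()
    nz, ny, nx = geom.volume_shape
    if position_vox is None:
        position_vox = np.array([nz / 2, ny / 2, nx / 2])
    base = position_vox * np.array([vz, vy, vx])
    pos = np.tile(base, (n_frames, 1))
    if jitter:
        pos = pos + rng.uniform(-0.5, 0.5, (n_frames, 3)) * [vz, vy, vx]
    em = EmitterTruth(0, "I", pos,
                      {"eGFP": np.full(n_frames, n_molecules, dtype=np.int64)},
                      0, n_frames)
    scene = Scene(cell_bounds=(nz * vz, ny * vy, nx * vx), emitters=[em],
                  n_frames=n_frames, frame_interval=geom.frame_interval)
    g = replace(geom, n_volumes=n_frames)
    vols, truth = render_volume_series(scene, g, camera, {"eGFP": egfp},
                                       psf, rng)
    return vols["eGFP"], pos


@pytest.fixture(scope="session")
def calibration_curve(geom_small, camera, psf, egfp):
    """Calibration fitted once on a default synthetic calibration field."""
    from escrtdyn.io import RunConfig
    from escrtdyn.pipeline import calibrate_from_field

    cfg = RunConfig(seed=42)
    cfg.geometry = {"volume_shape": (12, 48, 48), "planes_per_volume": 12}
    cfg.calibration = {"n_emitters": 300, "K_max": 4}
    rng = np.random.default_rng(42)
    return calibrate_from_field(cfg, rng)
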