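"""Forward imaging model: scenes -> EMCCD volume series.

Expected photoelectrons per emitter per frame are
``molecules * photon_rate * exposure * QE * bleach_survival``, spread over
voxels by the voxel-integrated Gaussian PSF; recorded counts follow the
scaled-Poisson EMCCD law of :class:`~escrtdyn.geometry.CameraModel` plus
Gaussian read noise. With ``skewed=True`` each plane is laterally displaced
by the stage-scan shear to emulate raw (pre-deskew) stacks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import (AcquisitionGeometry, CameraModel, FluorophoreModel,
                       PointSpreadFunction)
from .synthetic import Scene
from .volume_prep import VolumeSeries

__all__ = ["render_volume_series", "generate_calibration_field",
           "expected_unit_amplitude"]

_SQRT2 = np.sqrt(2.0)


def _axis_weights(center: float, sigma: float, n: int,
                  truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-integrated 1D Gaussian weights within +-truncate sigma."""
    lo = max(0, int(np.floor(center - truncate * sigma)))
    hi = min(n - 1, int(np.ceil(center + truncate * sigma)))
    if hi < lo:
        return np.empty(0, dtype=int), np.empty(0)
    idx = np.arange(lo, hi + 1)
    a = (idx - center - 0.5) / (_SQRT2 * sigma)
    b = (idx - center + 0.5) / (_SQRT2 * sigma)
    return idx, 0.5 * (erf(b) - erf(a))


def _add_spot(vol: np.ndarray, center_vox: np.ndarray, total_pe: float,
              sigmas_vox: tuple[float, float, float], shear_px: float = 0.0) -> None:
    """Accumulate one emitter's expected photoelectrons into a 3D volume."""
    nz, ny, nx = vol.shape
    cz, cy, cx = center_vox
    zi, wz = _axis_weights(cz, sigmas_vox[0], nz)
    yi, wy = _axis_weights(cy, sigmas_vox[1], ny)
    if len(zi) == 0 or len(yi) == 0:
        return
    if shear_px == 0.0:
        xi, wx = _axis_weights(cx, sigmas_vox[2], nx)
        if len(xi) == 0:
            return
        vol[np.ix_(zi, yi, xi)] += total_pe * (
            wz[:, None, None] * wy[None, :, None] * wx[None, None, :])
    else:
        for k, wzk in zip(zi, wz):
            xi, wx = _axis_weights(cx - k * shear_px, sigmas_vox[2], nx)
            if len(xi) == 0:
                continue
            vol[k][np.ix_(yi, xi)] += total_pe * wzk * (wy[:, None] * wx[None, :])


def _camera_counts(pe: np.ndarray, cam: CameraModel,
                   rng: np.random.Generator) -> np.ndarray:
    f2 = cam.excess_noise_factor ** 2
    signal = cam.gain * f2 * rng.poisson(pe / f2)
    counts = cam.offset + signal + rng.normal(0.0, cam.read_noise, size=pe.shape)
    return np.clip(counts, 0.0, None)


def expected_unit_amplitude(geom: AcquisitionGeometry, cam: CameraModel,
                            fluor: FluorophoreModel,
                            psf: PointSpreadFunction) -> float:
    """Analytic peak-voxel counts above background for one fluorophore.

    This is the 'unit intensity' the single-molecule calibration should
    recover (up to the few-percent difference between voxel-integrated data
    and a sampled-Gaussian fit, which cancels in the molecule conversion).
    """
    pe = fluor.photon_rate * geom.exposure_per_plane * cam.quantum_efficiency
    peak = 1.0
    for sig, step in zip(psf.sigmas_nm(), geom.voxel_size()):
        peak *= erf(step / (2 * _SQRT2 * sig))
    return cam.gain * pe * peak


def render_volume_series(scene: Scene,
                         geom: AcquisitionGeometry,
                         cam: CameraModel,
                         fluor: dict[str, FluorophoreModel],
                         psf: PointSpreadFunction,
                         rng: np.random.Generator,
                         skewed: bool = False,
                         ) -> tuple[dict[str, VolumeSeries], pd.DataFrame]:
    """Render a ground-truth scene into per-channel camera volume series.

    Returns the volumes (one :class:`VolumeSeries` per channel present in
    the scene and in ``fluor``) and a ground-truth table with the true
    per-frame positions, molecule counts and expected photoelectrons.
    """
    vz, vy, vx = geom.voxel_size()
    shape = geom.volume_shape
    if any(4 * s > ext * v for s, ext, v in
           zip(psf.sigmas_nm(), shape, (vz, vy, vx))):
        raise ValueError("PSF footprint larger than the rendered volume")
    sigmas_vox = psf.sigmas_voxels((vz, vy, vx))
    shear_px = geom.shear_per_plane / geom.pixel_size_xy if skewed else 0.0
    n_frames = min(scene.n_frames, geom.n_volumes)

    channels = [ch for ch in scene.channel_names if ch in fluor]
    if not channels and scene.emitters:
        raise ValueError("no fluorophore model matches the scene's channels")
    if not scene.emitters:
        channels = list(fluor)

    volumes: dict[str, np.ndarray] = {
        ch: np.empty((n_frames,) + shape) for ch in channels}
    truth_rows = []
    for ch in channels:
        fl = fluor[ch]
        bg_pe = (scene.background_photon_rate * (1 + scene.cytosol_haze_fraction)
                 * geom.exposure_per_plane * cam.quantum_efficiency)
        for t in range(n_frames):
            pe = np.full(shape, bg_pe)
            t_s = t * geom.frame_interval / 1000.0
            survival = float(fl.survival(t_s))
            for em in scene.emitters:
                n_mol = int(em.molecule_counts.get(ch, np.zeros(1))[t]) \
                    if t < len(em.molecule_counts.get(ch, ())) else 0
                if n_mol <= 0:
                    continue
                total_pe = (n_mol * fl.photon_rate * geom.exposure_per_plane
                            * cam.quantum_efficiency * survival)
                z, y, x = em.positions[t]
                _add_spot(pe, np.array([z / vz, y / vy, x / vx]), total_pe,
                          sigmas_vox, shear_px)
                truth_rows.append(dict(frame=t, emitter_id=em.emitter_id,
                                       channel=ch, class_label=em.class_label,
                                       z_nm=z, y_nm=y, x_nm=x,
                                       molecules=n_mol, expected_pe=total_pe))
            volumes[ch][t] = _camera_counts(pe, cam, rng)

    out = {ch: VolumeSeries(volumes[ch], geom, channel=ch, deskewed=not skewed,
                            provenance=[f"render(skewed={skewed})"])
           for ch in channels}
    cols = ["frame", "emitter_id", "channel", "class_label",
            "z_nm", "y_nm", "x_nm", "molecules", "expected_pe"]
    truth = pd.DataFrame(truth_rows, columns=cols)
    return out, truth


def generate_calibration_field(n_emitters: int,
                               geom: AcquisitionGeometry,
                               cam: CameraModel,
                               fluor: FluorophoreModel,
                               rng: np.random.Generator,
                               psf: PointSpreadFunction | None = None,
                               multiplicity_fractions: tuple[float, ...] = (0.7, 0.2, 0.1),
                               n_frames: int = 4,
                               bleach_prob_per_frame: float = 0.25,
                               background_photon_rate: float = 0.02,
                               spacing_px: int = 12,
                               ) -> tuple[VolumeSeries, dict]:
    """Render a sparse field of immobile single/double/triple fluorophores.

    Emulates purified eGFP adsorbed to a clean coverslip: low background,
    immobile emitters on a jittered grid, single-step photobleaching.
    Returns the volume series and a truth dict holding the analytic unit
    amplitude, positions (nm), multiplicities and per-frame fluorophore
    counts.
    """
    if n_emitters < 1:
        raise ValueError("n_emitters must be >= 1")
    if psf is None:
        from .geometry import default_psf
        psf = default_psf()
    fr = np.asarray(multiplicity_fractions, dtype=float)
    fr = fr / fr.sum()

    n_side = int(np.ceil(np.sqrt(n_emitters)))
    margin = spacing_px
    lateral = n_side * spacing_px + 2 * margin
    nz = geom.planes_per_volume
    geom_cal = replace(geom, volume_shape=(nz, lateral, lateral),
                       n_volumes=n_frames)
    vz, vy, vx = geom_cal.voxel_size()
    sigmas_vox = psf.sigmas_voxels((vz, vy, vx))

    mult = rng.choice(np.arange(1, len(fr) + 1), size=n_emitters, p=fr)
    gy, gx = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    grid = np.stack([gy.ravel(), gx.ravel()], axis=1)[:n_emitters]
    yx = (margin + grid * spacing_px + rng.uniform(-1, 1, size=(n_emitters, 2)))
    zc = nz / 2.0 + rng.uniform(-0.5, 0.5, size=n_emitters)
    pos_vox = np.column_stack([zc, yx])

    # single-step photobleaching of each fluorophore, frame by frame
    alive = mult.astype(np.int64).copy()
    counts = np.empty((n_frames, n_emitters), dtype=np.int64)
    for t in range(n_frames):
        counts[t] = alive
        alive = alive - rng.binomial(alive, bleach_prob_per_frame)

    bg_pe = background_photon_rate * geom_cal.exposure_per_plane * cam.quantum_efficiency
    pe_per_mol = fluor.photon_rate * geom_cal.exposure_per_plane * cam.quantum_efficiency
    data = np.empty((n_frames,) + geom_cal.volume_shape)
    for t in range(n_frames):
        pe = np.full(geom_cal.volume_shape, bg_pe)
        for i in range(n_emitters):
            if counts[t, i] > 0:
                _add_spot(pe, pos_vox[i], counts[t, i] * pe_per_mol, sigmas_vox)
        data[t] = _camera_counts(pe, cam, rng)

    vol = VolumeSeries(data, geom_cal, channel=fluor.channel_name,
                       deskewed=True, provenance=["generate_calibration_field"])
    truth = {
        "unit_amplitude": expected_unit_amplitude(geom_cal, cam, fluor, psf),
        "pe_per_molecule": pe_per_mol,
        "positions_nm": pos_vox * np.array([vz, vy, vx]),
        "multiplicities": mult,
        "counts": counts,
    }
    return vol, truth
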