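"""Volume-series container and preprocessing: flat-field, deskew, deconvolution.

Coordinate convention shared by all modules: arrays are (t, z, y, x), voxel
centers, 0-based indices, world coordinates in nm with x fastest. Raw
stage-scan stacks are sheared: the feature seen in plane ``k`` at camera
column ``x`` sits at world ``x + k * shear_per_plane``. ``deskew`` undoes the
shear by shifting plane ``k`` by ``+k * shear_per_plane`` onto an enlarged
canvas, after which z-spacing is ``stage_step_s * sin(sheet_angle)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, PointSpreadFunction

__all__ = ["VolumeSeries", "flatfield_correct", "deskew", "richardson_lucy",
           "subtract_offset"]


@dataclass
class VolumeSeries:
    """A 4D (t, z, y, x) intensity series in camera counts plus its geometry."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel: str = "eGFP"
    deskewed: bool = True
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4D (t, z, y, x)")
        if self.data.shape[1] != self.geometry.planes_per_volume:
            raise ValueError("z extent inconsistent with geometry")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def voxel_size(self) -> tuple[float, float, float]:
        return self.geometry.voxel_size()

    def log(self, msg: str) -> None:
        self.provenance.append(msg)

    def with_data(self, data: np.ndarray, **changes) -> "VolumeSeries":
        out = VolumeSeries(data=data, geometry=self.geometry,
                           channel=self.channel,
                           deskewed=changes.pop("deskewed", self.deskewed),
                           provenance=list(self.provenance))
        for k, v in changes.items():
            setattr(out, k, v)
        return out


def subtract_offset(vol: VolumeSeries, offset: float) -> VolumeSeries:
    """Subtract the camera offset, clamping at zero.

    Multiplicative deconvolution and photon-scaled statistics assume the
    data are proportional to photoelectrons, so the offset must go first.
    """
    out = vol.with_data(np.clip(vol.data - offset, 0.0, None))
    out.log(f"subtract_offset(offset={offset})")
    return out


def flatfield_correct(vol: VolumeSeries, illumination_profile: np.ndarray) -> VolumeSeries:
    """Divide each plane by the normalized illumination profile.

    The 2D profile (y, x) is normalized to unit mean so that the average
    intensity over the field is preserved.
    """
    profile = np.asarray(illumination_profile, dtype=np.float64)
    if profile.shape != vol.data.shape[2:]:
        raise ValueError("illumination profile shape must match (y, x) of the data")
    if np.any(profile <= 0):
        raise ValueError("illumination profile must be strictly positive")
    profile = profile / profile.mean()
    out = vol.with_data(vol.data / profile)
    out.log("flatfield_correct")
    return out


def deskew(vol: VolumeSeries, fill: str = "median") -> VolumeSeries:
    """Shift plane k laterally by k * shear_per_plane to orthogonal coordinates.

    Uses linear interpolation; newly exposed voxels are filled with the
    plane's median (``fill='median'``) or zero (``fill='zero'``), which is
    recorded in the provenance log.
    """
    if vol.deskewed:
        raise ValueError("volume is already deskewed")
    geom = vol.geometry
    shear_px = geom.shear_per_plane / geom.pixel_size_xy
    nt, nz, ny, nx = vol.data.shape
    pad = int(np.ceil((nz - 1) * shear_px))
    out = np.empty((nt, nz, ny, nx + pad), dtype=np.float64)
    for t in range(nt):
        for k in range(nz):
            plane = vol.data[t, k]
            cval = float(np.median(plane)) if fill == "median" else 0.0
            canvas = np.full((ny, nx + pad), cval)
            canvas[:, :nx] = plane
            # positive world shift of +k*shear maps output x to input x - shift
            out[t, k] = ndimage.shift(canvas, (0.0, k * shear_px), order=1,
                                      mode="grid-constant", cval=cval)
    res = vol.with_data(out, deskewed=True)
    res.log(f"deskew(shear_px={shear_px:.4f}, pad={pad}, fill={fill})")
    return res


def richardson_lucy(vol: VolumeSeries, psf: PointSpreadFunction,
                    iterations: int = 15, background: float = 0.0) -> VolumeSeries:
    """Richardson-Lucy deconvolution of each frame with the rasterised PSF.

    ``background`` counts are subtracted (clamped at zero) before iterating.
    Intended for visualization; the quantitative pipeline fits raw
    (non-deconvolved) volumes.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    from skimage.restoration import richardson_lucy as _rl

    kernel = psf.kernel(vol.voxel_size())
    s = kernel.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        warnings.warn("PSF kernel not normalized; renormalizing")
        kernel = kernel / s
    if any(ks > vs for ks, vs in zip(kernel.shape, vol.data.shape[1:])):
        raise ValueError("PSF kernel larger than the volume")
    data = np.clip(vol.data - background, 0.0, None)
    out = np.empty_like(data)
    for t in range(data.shape[0]):
        out[t] = _rl(data[t], kernel, num_iter=iterations, clip=False)
    out = np.clip(out, 0.0, None)
    res = vol.with_data(out)
    res.log(f"richardson_lucy(iterations={iterations}, background={background})")
    return res
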