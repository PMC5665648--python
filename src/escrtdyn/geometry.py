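"""Acquisition geometry, camera and fluorophore models.

These dataclasses collect the constants that connect the physical sample
(molecules emitting photons) to the recorded camera counts: the stage-scan
sampling geometry of the lattice light sheet, the EMCCD noise model, and the
per-channel photophysics. All lengths are in nm, times in ms unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "CameraModel",
    "FluorophoreModel",
    "PointSpreadFunction",
    "default_geometry",
    "default_camera",
    "default_egfp",
    "default_mcherry",
    "default_psf",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Stage-scan acquisition geometry of a lattice light-sheet time series.

    The sample stage is stepped along the s-axis at ``stage_step_s`` nm per
    plane; because the sheet is inclined at ``sheet_angle`` degrees to the
    coverslip, each step advances the optical section by
    ``stage_step_s * sin(sheet_angle)`` nm in z and shears the raw stack by
    ``stage_step_s * cos(sheet_angle)`` nm in x per plane.
    """

    pixel_size_xy: float = 97.7        # nm, camera pixel projected to sample
    stage_step_s: float = 500.0        # nm per plane along the stage axis
    sheet_angle: float = 31.5          # degrees between sheet and coverslip
    planes_per_volume: int = 30
    n_volumes: int = 60
    frame_interval: float = 850.0      # ms between volume starts
    exposure_per_plane: float = 21.0   # ms
    volume_shape: tuple[int, int, int] = (30, 512, 512)  # (z, y, x) voxels

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume_shape", tuple(self.volume_shape))
        if min(self.pixel_size_xy, self.stage_step_s, self.frame_interval,
               self.exposure_per_plane) <= 0:
            raise ValueError("geometry lengths and times must be positive")
        if not 0.0 < self.sheet_angle < 90.0:
            raise ValueError("sheet_angle must lie strictly between 0 and 90 degrees")
        if self.planes_per_volume < 1 or self.n_volumes < 1:
            raise ValueError("plane and volume counts must be positive")
        if self.frame_interval < self.planes_per_volume * self.exposure_per_plane:
            raise ValueError("frame_interval shorter than the summed plane exposures")
        if self.volume_shape[0] != self.planes_per_volume:
            raise ValueError("volume_shape z extent must equal planes_per_volume")

    @property
    def z_step(self) -> float:
        """Axial spacing of consecutive planes after deskew, nm."""
        return self.stage_step_s * math.sin(math.radians(self.sheet_angle))

    @property
    def shear_per_plane(self) -> float:
        """Lateral (x) displacement per plane in a raw stage-scan stack, nm."""
        return self.stage_step_s * math.cos(math.radians(self.sheet_angle))

    @property
    def series_duration(self) -> float:
        """Total duration of the time series, seconds."""
        return self.n_volumes * self.frame_interval / 1000.0

    def voxel_size(self) -> tuple[float, float, float]:
        """(z, y, x) voxel size in nm of the deskewed volume."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        if "volume_shape" in d:
            d["volume_shape"] = tuple(d["volume_shape"])
        return cls(**d)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD noise model.

    Recorded counts are modelled as
    ``offset + gain * F^2 * Poisson(pe / F^2) + Normal(0, read_noise)``
    where ``pe`` is the expected number of photoelectrons and ``F`` the
    excess noise factor of the gain register; this scaled-Poisson law has
    mean ``gain*pe`` and variance ``gain^2 * F^2 * pe`` above offset, the
    standard approximation for an EM gain register.
    """

    offset: float = 100.0
    gain: float = 50.0                 # counts per photoelectron
    excess_noise_factor: float = 1.41
    read_noise: float = 2.0            # counts, SD
    quantum_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 1.0 <= self.excess_noise_factor <= 2.0:
            raise ValueError("excess_noise_factor must be in [1, 2]")
        if not 0.0 < self.quantum_efficiency <= 1.0:
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.read_noise < 0:
            raise ValueError("read_noise must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FluorophoreModel:
    """Per-channel photophysics: emission rate and photobleaching."""

    photon_rate: float = 4.0   # detected photons per molecule per ms (pre-QE)
    bleach_rate: float = 0.0   # per second
    channel_name: str = "eGFP"

    def __post_init__(self) -> None:
        if self.photon_rate <= 0:
            raise ValueError("photon_rate must be positive")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")

    def survival(self, t_seconds: float | np.ndarray) -> float | np.ndarray:
        """Probability that a fluorophore has not bleached by time t."""
        return np.exp(-self.bleach_rate * np.asarray(t_seconds, dtype=float))

    def to_dict(self) -> dict:
        return asdict(self)


class PointSpreadFunction:
    """Anisotropic Gaussian PSF with lateral sigma_xy and axial sigma_z (nm).

    ``kernel(voxel_size)`` rasterises the PSF onto a voxel grid, integrating
    the Gaussian over each voxel (error-function differences) and normalising
    to unit sum.
    """

    def __init__(self, sigma_xy: float = 110.0, sigma_z: float = 380.0):
        if sigma_xy <= 0 or sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        self.sigma_xy = float(sigma_xy)
        self.sigma_z = float(sigma_z)

    def sigmas_nm(self) -> tuple[float, float, float]:
        """(z, y, x) sigmas in nm."""
        return (self.sigma_z, self.sigma_xy, self.sigma_xy)

    def sigmas_voxels(self, voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
        sz, sy, sx = self.sigmas_nm()
        return (sz / voxel_size[0], sy / voxel_size[1], sx / voxel_size[2])

    def kernel(self, voxel_size: tuple[float, float, float],
               truncate: float = 4.0) -> np.ndarray:
        """Voxel-integrated, unit-sum 3D kernel on the given (z, y, x) grid."""
        from scipy.special import erf

        axes = []
        for sig, step in zip(self.sigmas_nm(), voxel_size):
            half = int(np.ceil(truncate * sig / step))
            centers = np.arange(-half, half + 1) * step
            lo = (centers - step / 2) / (math.sqrt(2) * sig)
            hi = (centers + step / 2) / (math.sqrt(2) * sig)
            axes.append(0.5 * (erf(hi) - erf(lo)))
        k = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        return k / k.sum()

    def to_dict(self) -> dict:
        return {"sigma_xy": self.sigma_xy, "sigma_z": self.sigma_z}

    def __repr__(self) -> str:  # pragma: no cover
        return f"PointSpreadFunction(sigma_xy={self.sigma_xy}, sigma_z={self.sigma_z})"


def default_geometry(**overrides) -> AcquisitionGeometry:
    """Study-default acquisition geometry (overridable per field)."""
    return AcquisitionGeometry(**overrides)


def default_camera(**overrides) -> CameraModel:
    return CameraModel(**overrides)


def default_egfp(**overrides) -> FluorophoreModel:
    kw = dict(photon_rate=4.0, bleach_rate=0.005, channel_name="eGFP")
    kw.update(overrides)
    return FluorophoreModel(**kw)


def default_mcherry(**overrides) -> FluorophoreModel:
    # bleach_rate set so roughly one third of second-channel traces remain
    # analyzable over a 51 s series when onsets are uniform in time
    kw = dict(photon_rate=2.5, bleach_rate=0.04, channel_name="mCherry")
    kw.update(overrides)
    return FluorophoreModel(**kw)


def default_psf(**overrides) -> PointSpreadFunction:
    kw = dict(sigma_xy=110.0, sigma_z=380.0)
    kw.update(overrides)
    return PointSpreadFunction(**kw)
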