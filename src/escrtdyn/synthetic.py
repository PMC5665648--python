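"""Ground-truth generator for recruitment events, scenes and FRAP traces.

The generator emulates the statistical structure of ESCRT-III / Vps4
recruitment on yeast endosomes as seen in lattice light-sheet movies:

* events start abruptly (a burst of ~60 Snf7 / ~14 Vps24 / ~20 Vps4
  molecules), fluctuate with no net accumulation, and release all-or-none;
* lifetimes follow a bi-exponential mixture clamped to 3-45 s;
* Vps4 arrives and leaves in hexamers, so its count moves in steps of six;
* a cell contains a handful of mobile diffraction-limited class I emitters
  plus a few bright, static perivacuolar class II clusters whose signal is
  the sum of several asynchronous events.

Everything is driven by an explicit ``numpy.random.Generator`` so identical
seeds reproduce identical scenes bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry

__all__ = [
    "TraceParams",
    "CouplingSpec",
    "EmitterTruth",
    "Scene",
    "sample_lifetime",
    "simulate_trace",
    "build_scene",
    "generate_frap_trace",
    "snf7_params",
    "vps24_params",
    "vps4_params",
]


@dataclass(frozen=True)
class TraceParams:
    """Parameters of a single recruitment-event trace.

    ``quantum_step`` is 1 for ESCRT-III subunits and 6 for Vps4, whose
    content changes in whole hexamers. The lifetime law is the mixture
    ``w*Exp(tau1) + (1-w)*Exp(tau2)`` resampled into
    ``[min_lifetime, max_lifetime]``.
    """

    burst_mean: float = 60.0       # molecules at onset
    burst_sd: float = 15.0
    exchange_rate: float = 40.0    # exchange events per second
    quantum_step: int = 1          # molecules per exchange event
    lifetime_mix_weight: float = 0.7
    lifetime_tau1: float = 4.0     # s
    lifetime_tau2: float = 20.0    # s
    min_lifetime: float = 3.0      # s
    max_lifetime: float = 45.0     # s

    def __post_init__(self) -> None:
        if self.burst_mean <= 0:
            raise ValueError("burst_mean must be positive")
        if self.burst_sd < 0:
            raise ValueError("burst_sd must be non-negative")
        if self.quantum_step not in (1, 6):
            raise ValueError("quantum_step must be 1 (ESCRT-III) or 6 (Vps4)")
        if not 0.0 <= self.lifetime_mix_weight <= 1.0:
            raise ValueError("lifetime mixture weight must be in [0, 1]")
        if not 0 < self.lifetime_tau1 <= self.lifetime_tau2:
            raise ValueError("require 0 < tau1 <= tau2")
        if not self.min_lifetime < self.max_lifetime:
            raise ValueError("require min_lifetime < max_lifetime")
        if self.exchange_rate < 0:
            raise ValueError("exchange_rate must be non-negative")


def snf7_params(**overrides) -> TraceParams:
    """Snf7-eGFP-like event (tagged-subunit counts, before the x3 scaling)."""
    kw = dict(burst_mean=60.0, burst_sd=15.0, exchange_rate=40.0, quantum_step=1)
    kw.update(overrides)
    return TraceParams(**kw)


def vps24_params(**overrides) -> TraceParams:
    kw = dict(burst_mean=14.0, burst_sd=3.0, exchange_rate=6.0, quantum_step=1)
    kw.update(overrides)
    return TraceParams(**kw)


def vps4_params(**overrides) -> TraceParams:
    """Vps4-eGFP-like event: ~3 hexamers arrive, steps in multiples of six."""
    kw = dict(burst_mean=20.0, burst_sd=5.0, exchange_rate=1.5, quantum_step=6)
    kw.update(overrides)
    return TraceParams(**kw)


@dataclass(frozen=True)
class CouplingSpec:
    """How a second channel's counts follow the first channel's.

    The target series is ``q * round((ratio * source + noise) / q)`` inside
    the event window, which by construction correlates with the source at
    lag zero.
    """

    source_channel: str
    target_channel: str
    ratio: float = 1.0 / 3.0
    noise_sd: float = 3.0
    quantum_step: int = 6


@dataclass
class EmitterTruth:
    """Ground truth for one emitter: trajectory plus per-channel counts."""

    emitter_id: int
    class_label: str                        # "I" or "II"
    positions: np.ndarray                   # (n_frames, 3) nm, (z, y, x)
    molecule_counts: dict[str, np.ndarray]  # channel -> (n_frames,) ints
    onset_frame: int
    release_frame: int                      # first frame back at zero

    @property
    def channels(self) -> list[str]:
        return list(self.molecule_counts)


@dataclass
class Scene:
    """A cell's worth of ground-truth emitters inside a bounding box."""

    cell_bounds: tuple[float, float, float]   # (z, y, x) extents in nm
    emitters: list[EmitterTruth]
    background_photon_rate: float = 0.1       # photons per voxel per ms
    cytosol_haze_fraction: float = 0.0
    n_frames: int = 60
    frame_interval: float = 850.0             # ms

    def __post_init__(self) -> None:
        if min(self.cell_bounds) <= 0:
            raise ValueError("cell bounds must enclose a positive volume")
        if self.background_photon_rate < 0:
            raise ValueError("background_photon_rate must be non-negative")
        for em in self.emitters:
            pos = em.positions
            if np.any(pos < 0) or np.any(pos > np.asarray(self.cell_bounds)):
                raise ValueError(f"emitter {em.emitter_id} leaves cell_bounds")

    @property
    def channel_names(self) -> list[str]:
        names: list[str] = []
        for em in self.emitters:
            for ch in em.channels:
                if ch not in names:
                    names.append(ch)
        return names


def sample_lifetime(params: TraceParams, rng: np.random.Generator,
                    clamp: bool = True) -> float:
    """Draw one event lifetime (s) from the bi-exponential mixture.

    With ``clamp`` the draw is rejection-resampled into
    ``[min_lifetime, max_lifetime]``; with ``clamp=False`` the raw mixture
    draw is returned (useful for asymptotic checks).
    """
    while True:
        tau = params.lifetime_tau1 if rng.random() < params.lifetime_mix_weight \
            else params.lifetime_tau2
        t = rng.exponential(tau)
        if not clamp or params.min_lifetime <= t <= params.max_lifetime:
            return t


def lifetime_cdf(params: TraceParams, t: np.ndarray) -> np.ndarray:
    """CDF of the clamped bi-exponential lifetime law (for KS checks)."""
    w, t1, t2 = params.lifetime_mix_weight, params.lifetime_tau1, params.lifetime_tau2

    def raw(u):
        return w * (1 - np.exp(-u / t1)) + (1 - w) * (1 - np.exp(-u / t2))

    lo, hi = raw(params.min_lifetime), raw(params.max_lifetime)
    t = np.clip(np.asarray(t, dtype=float), params.min_lifetime, params.max_lifetime)
    return (raw(t) - lo) / (hi - lo)


def simulate_trace(params: TraceParams, frame_interval: float,
                   rng: np.random.Generator,
                   lifetime: float | None = None) -> tuple[np.ndarray, float]:
    """Simulate one event's per-frame molecule counts.

    The count jumps from zero to a quantised Gaussian burst at onset, then
    follows a zero-drift birth-death exchange process in units of
    ``quantum_step`` (Poisson arrivals balanced by binomial departures of
    equal mean), and drops to zero in a single frame at release.

    Parameters
    ----------
    frame_interval : float
        Frame spacing in ms.

    Returns
    -------
    counts : ndarray of int
        Molecule counts for each occupied frame (length >= 1).
    lifetime : float
        Event lifetime in seconds.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if lifetime is None:
        lifetime = sample_lifetime(params, rng)
    dt = frame_interval / 1000.0
    n_occ = max(1, int(round(lifetime / dt)))
    q = params.quantum_step

    burst = rng.normal(params.burst_mean, params.burst_sd)
    units = max(1, int(round(burst / q)))
    counts = np.empty(n_occ, dtype=np.int64)
    counts[0] = units * q
    lam = params.exchange_rate * dt
    for i in range(1, n_occ):
        arrivals = rng.poisson(lam)
        p_dep = min(1.0, lam / units) if units > 0 else 0.0
        departures = rng.binomial(units, p_dep)
        units = max(1, units + arrivals - departures)
        counts[i] = units * q
    return counts, float(lifetime)


def _place_trace(series: np.ndarray, counts: np.ndarray, onset: int) -> int:
    """Add an event's counts into a full-length series; returns release frame."""
    n = len(series)
    end = min(n, onset + len(counts))
    series[onset:end] += counts[: end - onset]
    return onset + len(counts)


def _coupled_series(source: np.ndarray, spec: CouplingSpec,
                    rng: np.random.Generator) -> np.ndarray:
    q = spec.quantum_step
    noisy = spec.ratio * source + rng.normal(0.0, spec.noise_sd, size=len(source))
    target = q * np.round(np.clip(noisy, 0, None) / q)
    target[source == 0] = 0
    return target.astype(np.int64)


def build_scene(geom: AcquisitionGeometry,
                trace_params: dict[str, TraceParams],
                rng: np.random.Generator,
                n_class_i: int = 7,
                n_class_ii: int = 2,
                diffusion_coefficient: float = 0.05,
                coupling: CouplingSpec | None = None,
                background_photon_rate: float = 0.1,
                cytosol_haze_fraction: float = 0.0,
                border_margin: float = 2000.0,
                class_ii_jitter_sd: float = 12.0) -> Scene:
    """Build a ground-truth scene of class I and class II emitters.

    Class I emitters diffuse (Brownian steps with the given
    ``diffusion_coefficient`` in um^2/s, reflecting at the cell bounds) and
    carry one recruitment event per primary channel; if ``coupling`` is
    given, a second channel's counts track the first at lag zero. Class II
    emitters are static clusters whose count series sums 3-5 asynchronous
    events, giving time-averaged totals 4-5x a single event.

    ``border_margin`` keeps initial positions away from the volume edge so
    that most class I tracks survive the 1.5 um border filter.
    """
    zmax = geom.planes_per_volume * geom.z_step
    ymax = geom.volume_shape[1] * geom.pixel_size_xy
    xmax = geom.volume_shape[2] * geom.pixel_size_xy
    bounds = np.array([zmax, ymax, xmax])
    if np.any(bounds <= 0):
        raise ValueError("cell volume is empty")
    n_frames = geom.n_volumes
    dt_s = geom.frame_interval / 1000.0
    step_sd = np.sqrt(2.0 * diffusion_coefficient * dt_s) * 1000.0  # nm

    margin = np.minimum(border_margin, bounds / 2.5)
    primary = list(trace_params)
    emitters: list[EmitterTruth] = []
    eid = 0

    for _ in range(n_class_i):
        pos = np.empty((n_frames, 3))
        pos[0] = rng.uniform(margin, bounds - margin)
        for f in range(1, n_frames):
            step = rng.normal(0.0, step_sd, size=3)
            nxt = pos[f - 1] + step
            # reflect at the cell boundary
            nxt = np.abs(nxt)
            nxt = np.where(nxt > bounds, 2 * bounds - nxt, nxt)
            pos[f] = np.clip(nxt, 0, bounds)
        counts: dict[str, np.ndarray] = {}
        onset = int(rng.integers(1, max(2, n_frames - 3)))
        release = onset
        for ch in primary:
            series = np.zeros(n_frames, dtype=np.int64)
            tr, _ = simulate_trace(trace_params[ch], geom.frame_interval, rng)
            release = max(release, min(n_frames, _place_trace(series, tr, onset)))
            counts[ch] = series
        if coupling is not None and coupling.source_channel in counts:
            counts[coupling.target_channel] = _coupled_series(
                counts[coupling.source_channel], coupling, rng)
        emitters.append(EmitterTruth(eid, "I", pos, counts, onset, release))
        eid += 1

    for _ in range(n_class_ii):
        center = rng.uniform(margin, bounds - margin)
        pos = center + rng.normal(0.0, class_ii_jitter_sd, size=(n_frames, 3))
        pos = np.clip(pos, 0, bounds)
        multiplicity = int(rng.integers(3, 6))
        counts = {}
        for ch in primary:
            # a cluster of MVBs hosts `multiplicity` asynchronous event
            # streams, each renucleating back to back, so the summed signal
            # persists for the whole series at ~multiplicity x one event's
            # level while fluctuating by single-event magnitudes
            series = np.zeros(n_frames, dtype=np.int64)
            for _k in range(multiplicity):
                sub = np.zeros(n_frames, dtype=np.int64)
                cursor = -int(rng.integers(0, 10))  # random phase
                while cursor < n_frames:
                    tr, _ = simulate_trace(trace_params[ch],
                                           geom.frame_interval, rng)
                    if cursor < 0:
                        tr = tr[-cursor:]
                        cursor = 0
                    if len(tr) == 0:
                        continue
                    cursor = _place_trace(sub, tr, cursor)
                series += sub
            counts[ch] = series
        if coupling is not None and coupling.source_channel in counts:
            counts[coupling.target_channel] = _coupled_series(
                counts[coupling.source_channel], coupling, rng)
        emitters.append(EmitterTruth(eid, "II", pos, counts, 0, n_frames))
        eid += 1

    return Scene(cell_bounds=tuple(bounds), emitters=emitters,
                 background_photon_rate=background_photon_rate,
                 cytosol_haze_fraction=cytosol_haze_fraction,
                 n_frames=n_frames, frame_interval=geom.frame_interval)


def generate_frap_trace(recovery_rate: float,
                        bleach_depth: float,
                        mobile_fraction: float,
                        noise_sd: float,
                        n_frames: int,
                        rng: np.random.Generator,
                        frame_interval: float = 0.2,
                        i0: float = 1.0,
                        n_prebleach: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a FRAP time series.

    Post-bleach intensity follows
    ``I(t) = I0 * (1 - depth * (mobile * exp(-k t) + (1 - mobile)))``
    with Gaussian noise; ``frame_interval`` is in seconds here (confocal
    FRAP sampling, not the volumetric frame clock).

    Returns (times_s, intensities); the bleach occurs at
    ``times[n_prebleach]``.
    """
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    times = np.arange(n_frames) * frame_interval
    ideal = np.full(n_frames, i0, dtype=float)
    post = times[n_prebleach:] - times[n_prebleach]
    ideal[n_prebleach:] = i0 * (1.0 - bleach_depth * (
        mobile_fraction * np.exp(-recovery_rate * post) + (1.0 - mobile_fraction)))
    return times, ideal + rng.normal(0.0, noise_sd, size=n_frames)
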