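"""Trace-level statistics of recruitment events.

Converts valid tracks into molecule-number time series and computes the
event statistics: lifetimes and their truncated bi-exponential fit,
maximum/mean accumulation and the Gaussian-mixture modes of the maxima,
lifetime cohorts, two-channel cross-correlations, fluctuation peaks,
productive-event classification (>= 4 Vps4 hexamers at any one time), and
single-exponential FRAP recovery fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.signal import find_peaks

from .calibration import (CalibrationCurve, amplitude_to_molecules,
                          molecules_to_hexamers)
from .stats import bootstrap_ci
from .tracking import Track

__all__ = ["MoleculeTrace", "EventSummary", "LifetimeFit", "CrossCorr",
           "CohortCurves", "extract_trace", "lifetime", "fit_biexponential",
           "accumulation_stats", "fit_max_mixture", "cohort_curves",
           "cross_correlate", "fluctuation_peaks", "classify_productive",
           "fit_frap", "summarize_event"]


@dataclass
class MoleculeTrace:
    """Per-event molecule-number time series with propagated errors."""

    track_id: int
    channel: str
    times: np.ndarray            # s, frame * frame_interval
    n: np.ndarray                # molecules per frame
    n_sd: np.ndarray             # propagated SD per frame
    local_background_n: np.ndarray   # molecule-equivalent local noise floor
    interpolated: np.ndarray     # bool mask of gap-filled frames
    class_label: str = "unclassified"
    censored: bool = False       # persistent: lifetime exceeds the series

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.n) == len(self.n_sd)):
            raise ValueError("trace arrays must have equal length")

    @property
    def lifetime_s(self) -> float:
        return lifetime(self)


@dataclass
class EventSummary:
    track_id: int
    channel: str
    lifetime: float
    max_accumulation: float
    mean_accumulation: float
    max_hexamers: int
    productive: bool
    n_fluctuation_peaks: int
    class_label: str
    censored: bool


@dataclass
class LifetimeFit:
    """Truncated bi-exponential MLE: w*Exp(tau1) + (1-w)*Exp(tau2)."""

    w: float
    tau1: float
    tau2: float
    w_ci: tuple[float, float]
    tau1_ci: tuple[float, float]
    tau2_ci: tuple[float, float]
    log_likelihood: float
    n_events: int
    collapsed: bool = False      # tau1 ~ tau2: effectively single-exponential


@dataclass
class CrossCorr:
    lags: np.ndarray                   # frames, symmetric around 0
    cc_intensity: np.ndarray           # mean per lag
    cc_intensity_sd: np.ndarray
    cc_derivative: np.ndarray
    cc_derivative_sd: np.ndarray
    n_traces: int
    min_lifetime_used: float


@dataclass
class CohortCurves:
    bin_edges: np.ndarray
    times: list[np.ndarray]            # per-cohort time axis from onset, s
    means: list[np.ndarray]
    lo: list[np.ndarray]               # lower 95% bound
    hi: list[np.ndarray]
    counts: list[int]
    dropped: list[tuple[float, float, int]] = field(default_factory=list)


def extract_trace(track: Track, cal: CalibrationCurve, channel: str,
                  frame_interval: float,
                  exposure: float | None = None) -> MoleculeTrace:
    """Convert a track's fitted amplitudes into a molecule-number trace.

    Gap frames are filled by linear interpolation of N (flagged in
    ``interpolated``). The local background companion is the fit-window
    residual noise expressed in molecule units.
    """
    if cal is None:
        raise ValueError("calibration required")
    frames = track.frames
    full = np.arange(frames[0], frames[-1] + 1)
    amp = np.array([s.amplitude for s in track.spots])
    amp_sd = np.array([s.amplitude_sd for s in track.spots])
    res_sd = np.array([s.residual_sd for s in track.spots])
    n_occ, sd_occ = amplitude_to_molecules(amp, amp_sd, cal, exposure)
    mu1 = cal.unit_at(exposure)

    n = np.interp(full, frames, n_occ)
    sd = np.interp(full, frames, sd_occ)
    bg = np.interp(full, frames, res_sd / mu1)
    interp = ~np.isin(full, frames)
    times = full * frame_interval / 1000.0
    return MoleculeTrace(track_id=track.track_id, channel=channel,
                         times=times, n=n, n_sd=sd, local_background_n=bg,
                         interpolated=interp, class_label=track.class_label,
                         censored="persistent" in track.flags)


def lifetime(trace: MoleculeTrace) -> float:
    """Event lifetime in s: occupied frames times the frame interval."""
    if len(trace.times) < 2:
        dt = 0.85
    else:
        dt = float(trace.times[1] - trace.times[0])
    return len(trace.times) * dt


def _trunc_biexp_nll(params: np.ndarray, t: np.ndarray, t0: float) -> float:
    w = 1.0 / (1.0 + np.exp(-params[0]))
    tau1, tau2 = np.exp(params[1]), np.exp(params[2])
    pdf = (w * np.exp(-t / tau1) / tau1 + (1 - w) * np.exp(-t / tau2) / tau2)
    surv0 = w * np.exp(-t0 / tau1) + (1 - w) * np.exp(-t0 / tau2)
    return -np.sum(np.log(np.maximum(pdf, 1e-300))) + len(t) * np.log(max(surv0, 1e-300))


def fit_biexponential(lifetimes: np.ndarray, min_observable: float = 0.0,
                      n_boot: int = 200, seed: int = 0,
                      min_events: int = 100) -> LifetimeFit:
    """Maximum-likelihood bi-exponential fit, left-truncated at min_observable.

    Confidence intervals are percentile bootstrap (``n_boot`` resamples).
    If the two time constants collapse (within 5%), the fit is reported as
    effectively single-exponential (``collapsed=True``).
    """
    t = np.asarray(lifetimes, dtype=float)
    t = t[np.isfinite(t) & (t >= min_observable)]
    if len(t) < min_events:
        raise ValueError(f"need >= {min_events} uncensored lifetimes, got {len(t)}")

    def fit_once(tt: np.ndarray) -> tuple[float, float, float, float]:
        best, bval = None, np.inf
        m = tt.mean()
        for w0, r1, r2 in ((0.5, 0.5, 2.0), (0.7, 0.3, 3.0), (0.3, 0.8, 1.5)):
            x0 = np.array([np.log(w0 / (1 - w0)), np.log(r1 * m), np.log(r2 * m)])
            sol = optimize.minimize(_trunc_biexp_nll, x0, args=(tt, min_observable),
                                    method="Nelder-Mead",
                                    options=dict(maxiter=2000, xatol=1e-6, fatol=1e-9))
            if sol.fun < bval:
                best, bval = sol.x, sol.fun
        w = 1.0 / (1.0 + np.exp(-best[0]))
        tau1, tau2 = np.exp(best[1]), np.exp(best[2])
        if tau1 > tau2:
            tau1, tau2, w = tau2, tau1, 1.0 - w
        return w, tau1, tau2, -bval

    w, tau1, tau2, ll = fit_once(t)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bw, b1, b2, _ = fit_once(rng.choice(t, size=len(t), replace=True))
        boots.append((bw, b1, b2))
    boots = np.asarray(boots) if boots else np.empty((0, 3))

    def ci(col):
        if len(boots) == 0:
            return (np.nan, np.nan)
        return tuple(np.percentile(boots[:, col], [2.5, 97.5]))

    collapsed = abs(tau2 - tau1) <= 0.05 * tau2
    if collapsed:
        w = 1.0
    return LifetimeFit(w=w, tau1=tau1, tau2=tau2, w_ci=ci(0), tau1_ci=ci(1),
                       tau2_ci=ci(2), log_likelihood=ll, n_events=len(t),
                       collapsed=collapsed)


def accumulation_stats(trace: MoleculeTrace) -> tuple[float, float]:
    """(max, time-averaged mean) molecule accumulation over occupied frames."""
    if len(trace.n) == 0:
        raise ValueError("empty trace")
    return float(trace.n.max()), float(trace.n.mean())


def fit_max_mixture(values: np.ndarray, K: int = 2, n_init: int = 8,
                    seed: int = 0, min_samples: int = 200) -> "MixtureFit":
    """Unconstrained Gaussian mixture of maximum accumulations, up to K
    components chosen by BIC.

    Multi-start EM; the lowest-mean component is reported first, its
    mean +- SD being the distribution's principal mode. A genuinely
    unimodal sample therefore collapses to a single component instead of
    being split in two; degenerate input (all values equal) is reported as
    a single zero-width component.
    """
    from sklearn.mixture import GaussianMixture
    from .calibration import MixtureFit

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < min_samples:
        raise ValueError(f"need >= {min_samples} values, got {len(x)}")
    if np.ptp(x) == 0:
        v = float(x[0, 0])
        return MixtureFit(K=1, weights=np.array([1.0]), means=np.array([v]),
                          sds=np.array([0.0]), log_likelihood=np.inf,
                          bic=-np.inf, converged=True, n_points=len(x))
    best = None
    for k in range(1, K + 1):
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed,
                             covariance_type="full", reg_covar=1e-6,
                             tol=1e-7, max_iter=5000)
        gm.fit(x)
        if gm.converged_ and (best is None or gm.bic(x) < best.bic(x)):
            best = gm
    if best is None:
        raise RuntimeError("EM did not converge for the max-accumulation mixture")
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.reshape(-1)[order])
    weights = best.weights_[order]
    ll = float(best.score(x) * len(x))
    return MixtureFit(K=best.n_components, weights=weights, means=means,
                      sds=sds, log_likelihood=ll, bic=float(best.bic(x)),
                      converged=True, n_points=len(x))


def cohort_curves(traces: list[MoleculeTrace],
                  bin_edges: tuple[float, ...] = (3.0, 5.0, 10.0, 51.0),
                  min_count: int = 10, n_boot: int = 500,
                  seed: int = 0) -> CohortCurves:
    """Average onset-aligned traces within lifetime cohorts.

    Traces are grouped by lifetime into ``[edge_i, edge_{i+1})`` bins,
    aligned at onset, and averaged per time point over the traces still
    occupied there; the band is a percentile-bootstrap 95% confidence
    bound of the mean. Cohorts below ``min_count`` traces are dropped and
    logged in ``dropped``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    out = CohortCurves(bin_edges=edges, times=[], means=[], lo=[], hi=[],
                       counts=[])
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        group = [tr for tr in traces
                 if not tr.censored and lo_e <= tr.lifetime_s < hi_e]
        if len(group) < min_count:
            out.dropped.append((float(lo_e), float(hi_e), len(group)))
            continue
        dt = float(group[0].times[1] - group[0].times[0]) \
            if len(group[0].times) > 1 else 0.85
        max_len = max(len(tr.n) for tr in group)
        mat = np.full((len(group), max_len), np.nan)
        for i, tr in enumerate(group):
            mat[i, :len(tr.n)] = tr.n
        mean = np.nanmean(mat, axis=0)
        lo_b = np.empty(max_len)
        hi_b = np.empty(max_len)
        for j in range(max_len):
            col = mat[:, j]
            col = col[~np.isnan(col)]
            if len(col) >= 2:
                lo_b[j], hi_b[j] = bootstrap_ci(
                    col, np.mean, level=0.95, n_boot=n_boot,
                    seed=int(rng.integers(2 ** 31)))
            else:
                lo_b[j] = hi_b[j] = mean[j]
        out.times.append(np.arange(max_len) * dt)
        out.means.append(mean)
        out.lo.append(lo_b)
        out.hi.append(hi_b)
        out.counts.append(len(group))
    return out


def _pearson_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    # positive lag: b delayed relative to a peaks at that lag
    if lag >= 0:
        x, y = a[: len(a) - lag] if lag else a, b[lag:]
    else:
        x, y = a[-lag:], b[: len(b) + lag]
    if len(x) < 3:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def cross_correlate(traces_a: list[MoleculeTrace],
                    traces_b: list[MoleculeTrace],
                    max_lag: int = 6,
                    min_lifetime: float = 11.0) -> CrossCorr:
    """Average per-pair Pearson cross-correlation of paired two-channel traces.

    For each pair (same track, two channels) the mean-subtracted intensity
    and its first difference are correlated at every lag; pairs with
    lifetime below ``min_lifetime`` seconds are excluded, following the
    convention of restricting the correlation analysis to long events.
    """
    if len(traces_a) != len(traces_b):
        raise ValueError("trace lists must be paired")
    lags = np.arange(-max_lag, max_lag + 1)
    cc_i, cc_d = [], []
    for ta, tb in zip(traces_a, traces_b):
        if min(ta.lifetime_s, tb.lifetime_s) < min_lifetime:
            continue
        n = min(len(ta.n), len(tb.n))
        a, b = ta.n[:n], tb.n[:n]
        da, db = np.diff(a), np.diff(b)
        cc_i.append([_pearson_at_lag(a, b, int(l)) for l in lags])
        cc_d.append([_pearson_at_lag(da, db, int(l)) for l in lags])
    if not cc_i:
        raise ValueError(f"no pairs with lifetime >= {min_lifetime} s")
    cc_i = np.asarray(cc_i)
    cc_d = np.asarray(cc_d)
    return CrossCorr(lags=lags,
                     cc_intensity=np.nanmean(cc_i, axis=0),
                     cc_intensity_sd=np.nanstd(cc_i, axis=0),
                     cc_derivative=np.nanmean(cc_d, axis=0),
                     cc_derivative_sd=np.nanstd(cc_d, axis=0),
                     n_traces=len(cc_i), min_lifetime_used=min_lifetime)


def fluctuation_peaks(trace: MoleculeTrace, min_prominence: float = 6.0,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima with topographic prominence >= min_prominence molecules.

    Returns (times_s, heights, prominences); heights are molecules above
    the surrounding minima (i.e. the prominences' base-relative values).
    """
    if len(trace.n) < 3:
        return np.empty(0), np.empty(0), np.empty(0)
    idx, props = find_peaks(trace.n, prominence=min_prominence)
    return trace.times[idx], trace.n[idx], props["prominences"]


def classify_productive(trace: MoleculeTrace) -> bool:
    """Productive iff the trace reaches >= 4 Vps4 hexamers at any one time."""
    if len(trace.n) == 0:
        return False
    return molecules_to_hexamers(float(np.clip(trace.n.max(), 0, None))) >= 4


def summarize_event(trace: MoleculeTrace,
                    peak_prominence: float = 6.0) -> EventSummary:
    mx, mn = accumulation_stats(trace)
    _, _, proms = fluctuation_peaks(trace, peak_prominence)
    return EventSummary(track_id=trace.track_id, channel=trace.channel,
                        lifetime=trace.lifetime_s, max_accumulation=mx,
                        mean_accumulation=mn,
                        max_hexamers=molecules_to_hexamers(max(mx, 0.0)),
                        productive=classify_productive(trace),
                        n_fluctuation_peaks=len(proms),
                        class_label=trace.class_label,
                        censored=trace.censored)


@dataclass
class FrapFit:
    rate: float                 # 1/s
    rate_ci: tuple[float, float]
    mobile_fraction: float
    plateau: float
    no_recovery: bool


def fit_frap(times: np.ndarray, intensities: np.ndarray,
             bleach_frame: int | None = None,
             reference: np.ndarray | None = None) -> FrapFit:
    """Single-exponential FRAP recovery fit.

    The trace is normalized to its first (pre-bleach) frame; if a
    ``reference`` region trace is supplied, acquisition bleaching is first
    corrected by dividing out its fitted exponential decay. The bleach
    frame defaults to the largest single-frame drop. The recovery model is
    ``I(t) = plateau - (plateau - I_bleach) * exp(-k (t - t_b))``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if reference is not None:
        ref = np.asarray(reference, dtype=float) / reference[0]
        k_ref = np.polyfit(t, np.log(np.maximum(ref, 1e-9)), 1)[0]
        y = y / np.exp(k_ref * t)
    y = y / y[0]
    if bleach_frame is None:
        bleach_frame = int(np.argmin(np.diff(y)) + 1)
    tp = t[bleach_frame:] - t[bleach_frame]
    yp = y[bleach_frame:]
    i_bleach = yp[0]
    pre = float(np.mean(y[:bleach_frame]))

    def model(tt, k, plateau):
        return plateau - (plateau - i_bleach) * np.exp(-k * tt)

    try:
        span = max(tp[-1], 1e-6)
        popt, pcov = optimize.curve_fit(
            model, tp, yp, p0=[1.0 / span, min(yp[-1] + 1e-3, 1.0)],
            bounds=([0.0, i_bleach], [np.inf, 1.5]), maxfev=5000)
        k, plateau = popt
        k_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    except RuntimeError:
        k, plateau, k_sd = 0.0, i_bleach, np.inf
    ci = (max(0.0, k - 1.96 * k_sd), k + 1.96 * k_sd)
    denom = pre - i_bleach
    mobile = float((plateau - i_bleach) / denom) if denom > 1e-9 else 0.0
    noise = float(np.std(np.diff(yp))) / np.sqrt(2) if len(yp) > 2 else 0.0
    no_recovery = (plateau - i_bleach) <= max(2 * noise, 1e-3)
    return FrapFit(rate=float(k), rate_ci=ci, mobile_fraction=mobile,
                   plateau=float(plateau), no_recovery=bool(no_recovery))
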