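"""Single-fluorophore intensity calibration and molecule arithmetic.

The calibration field yields a distribution of fitted spot amplitudes that
is a superposition of 1-, 2-, 3-mer populations. Because k independent
fluorophores emit k-fold the photons with k-fold the shot variance, the
mixture is fit under the physical constraint ``mean_k = k*mu1``,
``var_k = k*sigma1^2``; the first component's mean is the single-molecule
unit intensity. Spot amplitudes are then converted to molecule numbers
with first-order error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MixtureFit", "CalibrationCurve", "fit_single_molecule_mixture",
           "amplitude_to_molecules", "scale_snf7", "molecules_to_hexamers",
           "stoichiometry_ratio", "CalibrationError"]

SNF7_TAG_FACTOR = 3.0  # tagged Snf7 is interspersed ~1:2 with untagged Snf7


class CalibrationError(RuntimeError):
    pass


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_points: int


@dataclass
class CalibrationCurve:
    """Single-fluorophore unit intensity (counts) at a reference exposure."""

    unit_intensity: float
    unit_intensity_sd: float
    exposure_reference: float      # ms
    n_samples: int
    mixture: MixtureFit | None = None

    def unit_at(self, exposure: float | None = None) -> float:
        """Unit intensity rescaled linearly to another exposure."""
        if exposure is None:
            return self.unit_intensity
        return self.unit_intensity * exposure / self.exposure_reference

    def unit_sd_at(self, exposure: float | None = None) -> float:
        if exposure is None:
            return self.unit_intensity_sd
        return self.unit_intensity_sd * exposure / self.exposure_reference


def _constrained_em(x: np.ndarray, K: int, max_iter: int = 500,
                    tol: float = 1e-9) -> MixtureFit:
    """EM for the constrained mixture sum_k w_k N(k*mu1, k*sigma1^2)."""
    n = len(x)
    ks = np.arange(1, K + 1, dtype=float)
    # moment-based init: assume the lowest populated mode is the monomer
    mu1 = float(np.percentile(x, 35)) or float(np.mean(x))
    sigma1 = max(float(np.std(x)) / np.sqrt(K), 1e-8 * abs(mu1) + 1e-12)
    w = np.full(K, 1.0 / K)

    def log_comp(mu1, sigma1):
        var = np.maximum(ks * sigma1 ** 2, 1e-300)
        return (-0.5 * np.log(2 * np.pi * var)[None, :]
                - (x[:, None] - ks[None, :] * mu1) ** 2 / (2 * var[None, :]))

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        lp = log_comp(mu1, sigma1) + np.log(np.maximum(w, 1e-300))[None, :]
        m = lp.max(axis=1, keepdims=True)
        p = np.exp(lp - m)
        tot = p.sum(axis=1, keepdims=True)
        r = p / tot
        ll = float(np.sum(np.log(tot.ravel()) + m.ravel()))
        nk = r.sum(axis=0)
        w = nk / n
        mu1 = float(np.sum(r * x[:, None]) / max(np.sum(nk * ks), 1e-300))
        s2 = float(np.sum(r * (x[:, None] - ks[None, :] * mu1) ** 2 / ks[None, :])
                   / max(n, 1))
        sigma1 = max(np.sqrt(s2), 1e-12)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    n_par = (K - 1) + 2
    bic = -2.0 * ll_old + n_par * np.log(n)
    return MixtureFit(K=K, weights=w, means=ks * mu1,
                      sds=np.sqrt(ks) * sigma1, log_likelihood=ll_old,
                      bic=bic, converged=converged, n_points=n)


def _mu1_observed_sd(x: np.ndarray, fit: MixtureFit) -> float:
    """SD of mu1 from the observed information (numeric second derivative
    of the mixture log-likelihood in mu1 at the MLE)."""
    mu1 = fit.means[0]
    sigma1 = fit.sds[0]
    ks = np.arange(1, fit.K + 1, dtype=float)
    w = np.maximum(fit.weights, 1e-300)

    def ll(m):
        var = ks * sigma1 ** 2
        lp = (np.log(w)[None, :] - 0.5 * np.log(2 * np.pi * var)[None, :]
              - (x[:, None] - ks[None, :] * m) ** 2 / (2 * var[None, :]))
        mx = lp.max(axis=1, keepdims=True)
        return float(np.sum(np.log(np.exp(lp - mx).sum(axis=1)) + mx.ravel()))

    h = 1e-4 * max(abs(mu1), 1.0)
    d2 = (ll(mu1 + h) - 2 * ll(mu1) + ll(mu1 - h)) / h ** 2
    if d2 >= 0:
        return sigma1 / np.sqrt(len(x))  # fallback: single-component scale
    return float(1.0 / np.sqrt(-d2))


def fit_single_molecule_mixture(intensities: np.ndarray,
                                K_max: int = 4,
                                exposure_reference: float = 21.0,
                                min_samples: int = 200) -> CalibrationCurve:
    """Fit constrained Gaussian mixtures for K = 1..K_max; pick K by BIC.

    ``intensities`` are significance-accepted spot amplitudes from the
    calibration field, all recorded at ``exposure_reference`` ms.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_samples:
        raise CalibrationError(
            f"need >= {min_samples} accepted amplitudes, got {len(x)}")
    fits = []
    for K in range(1, K_max + 1):
        f = _constrained_em(x, K)
        if f.converged:
            fits.append(f)
    if not fits:
        raise CalibrationError("constrained EM failed to converge for all K")
    best = min(fits, key=lambda f: f.bic)
    mu1 = float(best.means[0])
    if mu1 <= 0:
        raise CalibrationError("non-positive unit intensity")
    return CalibrationCurve(unit_intensity=mu1,
                            unit_intensity_sd=_mu1_observed_sd(x, best),
                            exposure_reference=exposure_reference,
                            n_samples=len(x), mixture=best)


def amplitude_to_molecules(amplitude: float | np.ndarray,
                           amplitude_sd: float | np.ndarray,
                           cal: CalibrationCurve,
                           exposure: float | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Convert counts to molecule numbers with propagated uncertainty.

    ``N = A / mu1`` and
    ``sigma_N = sqrt((sigma_A/mu1)^2 + (A*sigma_mu1/mu1^2)^2)`` -- the
    square root of the squared sums of the fit and calibration
    uncertainties. N may be non-integer; negative amplitudes keep their
    sign (baseline noise).
    """
    mu1 = cal.unit_at(exposure)
    smu = cal.unit_sd_at(exposure)
    if mu1 <= 0:
        raise CalibrationError("calibration unit intensity must be positive")
    a = np.asarray(amplitude, dtype=float)
    sa = np.asarray(amplitude_sd, dtype=float)
    n = a / mu1
    sn = np.sqrt((sa / mu1) ** 2 + (a * smu / mu1 ** 2) ** 2)
    return n, sn


def scale_snf7(n_tagged: float | np.ndarray,
               factor: float = SNF7_TAG_FACTOR) -> float | np.ndarray:
    """Scale tagged-Snf7 counts to total Snf7 (default x3 interspersion)."""
    return factor * np.asarray(n_tagged, dtype=float) if np.ndim(n_tagged) \
        else factor * float(n_tagged)


def molecules_to_hexamers(n: float) -> int:
    """Nearest whole number of hexamers (half rounds up): 20 -> 3, 11 -> 2."""
    if np.ndim(n):
        arr = np.asarray(n, dtype=float)
        if np.any(arr < 0):
            raise ValueError("molecule count must be non-negative")
        return np.floor(arr / 6.0 + 0.5).astype(int)
    if n < 0:
        raise ValueError("molecule count must be non-negative")
    return int(np.floor(n / 6.0 + 0.5))


def stoichiometry_ratio(traces_a, traces_b, scale_a: float = 1.0,
                        ) -> tuple[float, float, int]:
    """Mean per-event ratio of channel A to channel B accumulation.

    ``traces_a`` / ``traces_b`` are paired sequences of per-frame molecule
    counts (or objects with an ``n`` attribute). Events with zero mean in
    channel B are excluded; returns (mean ratio, SE, n_excluded).
    """
    if len(traces_a) == 0 or len(traces_b) == 0:
        raise ValueError("both trace sets must be non-empty")
    if len(traces_a) != len(traces_b):
        raise ValueError("trace sets must be paired")

    def mean_of(tr):
        arr = np.asarray(getattr(tr, "n", tr), dtype=float)
        return float(arr.mean())

    ratios, excluded = [], 0
    for ta, tb in zip(traces_a, traces_b):
        mb = mean_of(tb)
        if mb == 0:
            excluded += 1
            continue
        ratios.append(scale_a * mean_of(ta) / mb)
    if not ratios:
        raise ValueError("no events with non-zero channel-B accumulation")
    r = np.asarray(ratios)
    se = float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0
    return float(r.mean()), se, excluded
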