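"""Distribution-comparison utilities: KS, permutation tests, bootstrap.

The permutation test enumerates all group assignments exhaustively when
their number does not exceed ``n_perm`` (the p-value is then exact);
otherwise it Monte-Carlo samples with the add-one estimator
``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "ks_two_sample", "permutation_test", "bootstrap_ci"]


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    n_permutations: int = 0
    seed: int | None = None
    exact: bool = False


def ks_two_sample(x, y, mode: str = "asymptotic") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_x - ECDF_y|.

    The asymptotic p-value is the default (the sample sizes in this kind
    of dataset run to thousands); ``mode='exact'`` is available for small
    samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp" if mode == "asymptotic" else "exact")
    return TestResult(method="ks_two_sample", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_x=len(x), n_y=len(y),
                      exact=(mode == "exact"))


def _stat_fn(statistic: str):
    if statistic == "mean":
        return np.mean
    if statistic == "median":
        return np.median
    raise ValueError("statistic must be 'mean' or 'median'")


def permutation_test(x, y, statistic: str = "mean",
                     n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """Two-sided two-sample permutation test on a difference of means/medians.

    Exhaustive enumeration of the C(n_x+n_y, n_x) group assignments is
    used automatically when feasible (p is then the exact fraction of
    arrangements at least as extreme, including the observed one).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) < 4:
        raise ValueError("combined sample size must be >= 4")
    fn = _stat_fn(statistic)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(method=f"permutation_{statistic}", statistic=0.0,
                          p_value=1.0, n_x=len(x), n_y=len(y),
                          n_permutations=0, seed=seed, exact=True)
    obs = abs(fn(x) - fn(y))
    n, nx = len(pooled), len(x)

    from math import comb
    total = comb(n, nx)
    if total <= n_perm:
        count = 0
        idx_all = np.arange(n)
        for pick in combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(pick)] = True
            d = abs(fn(pooled[sel]) - fn(pooled[~sel]))
            if d >= obs - 1e-12:
                count += 1
        p = count / total
        return TestResult(method=f"permutation_{statistic}", statistic=float(obs),
                          p_value=float(p), n_x=nx, n_y=len(y),
                          n_permutations=total, seed=seed, exact=True)

    rng = np.random.default_rng(seed)
    mat = np.tile(pooled, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    dx = fn(mat[:, :nx], axis=1)
    dy = fn(mat[:, nx:], axis=1)
    count = int(np.sum(np.abs(dx - dy) >= obs - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return TestResult(method=f"permutation_{statistic}", statistic=float(obs),
                      p_value=float(p), n_x=nx, n_y=len(y),
                      n_permutations=n_perm, seed=seed, exact=False)


def bootstrap_ci(values, statistic=np.mean, level: float = 0.95,
                 n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        s = float(statistic(v))
        return (s, s)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    try:
        stats = statistic(v[idx], axis=1)
    except TypeError:
        stats = np.array([statistic(v[i]) for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
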