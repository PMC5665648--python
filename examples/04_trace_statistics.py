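"""Event-level statistics: lifetimes, accumulation modes, productive events.

Simulates a population of Vps4-like recruitment events (bursts of ~20
molecules arriving in hexamer steps, bi-exponential 3-45 s lifetimes),
then recomputes the statistics the traces are summarized by: the truncated
bi-exponential lifetime fit, the Gaussian-mixture mode of maximum
accumulation, and the productive-event fraction (>= 4 hexamers at any one
time).
"""

import numpy as np

from escrtdyn import (MoleculeTrace, classify_productive, fit_biexponential,
                      fit_max_mixture, sample_lifetime, simulate_trace,
                      vps4_params)

rng = np.random.default_rng(2)
params = vps4_params()

lifetimes, maxima, productive = [], [], 0
for _ in range(2000):
    counts, life = simulate_trace(params, 850.0, rng)
    lifetimes.append(life)
    maxima.append(counts.max())
    tr = MoleculeTrace(track_id=0, channel="Vps4-eGFP",
                       times=np.arange(len(counts)) * 0.85,
                       n=counts.astype(float), n_sd=np.ones(len(counts)),
                       local_background_n=np.zeros(len(counts)),
                       interpolated=np.zeros(len(counts), bool))
    productive += classify_productive(tr)

fit = fit_biexponential(np.asarray(lifetimes), min_observable=3.0, n_boot=0)
print(f"lifetime fit: w={fit.w:.2f}, tau1={fit.tau1:.1f} s, "
      f"tau2={fit.tau2:.1f} s (n={fit.n_events})")
# the 3-45 s clamp on the generator reshapes the observable mixture, so the
# fitted time constants describe the clamped law, not the raw tau1/tau2

mix = fit_max_mixture(np.asarray(maxima, float), K=2, seed=0)
print(f"maximum accumulation: first mode {mix.means[0]:.1f} "
      f"+- {mix.sds[0]:.1f} molecules "
      f"(~{mix.means[0] / 6:.1f} hexamers, K={mix.K})")

print(f"productive events (>= 4 hexamers at some time): "
      f"{100 * productive / 2000:.0f}%")
# short-lived events rarely reach 4 hexamers; the productive fraction is
# dominated by the longer-lived component of the lifetime mixture
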