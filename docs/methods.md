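# Methods

This note documents the models behind `escrtdyn`, the defaults and their
units, the numerical choices, and what the synthetic data do and do not
establish about real microscope data.

## Acquisition geometry and camera model

A lattice light-sheet volume is acquired by stepping the sample stage along
its s-axis; with a stage step `s` and sheet angle `θ` to the coverslip,
each plane advances the optical section by `s·sin θ` in z and shears the
raw stack laterally by `s·cos θ` per plane. Defaults
(`AcquisitionGeometry`): 97.7 nm pixels (50 µm / 512 px), 500 nm stage
steps, θ = 31.5° (z-step 261 nm), 30 planes per volume, 21 ms exposure per
plane, 850 ms per volume, 60 volumes (51 s series), 512×512×30 voxels.
All are configuration, not constants.

Recorded counts follow a scaled-Poisson EMCCD law:

    counts = offset + gain · F² · Poisson(pe / F²) + Normal(0, read_noise)

with `pe` the expected photoelectrons and `F` the excess-noise factor of
the electron-multiplying register. This has mean `gain·pe` and variance
`gain²·F²·pe` — the standard second-order approximation of the EM gain
cascade; the full per-electron gain distribution is not modeled. Defaults:
offset 100, gain 50 counts/pe, F = 1.41, read noise 2 counts, QE 0.9.

The photon budget (4 detected photons·molecule⁻¹·ms⁻¹ for eGFP, cytosol
background 0.1 photons·voxel⁻¹·ms⁻¹) was chosen analytically so that a
3-eGFP diffraction-limited spot yields a fitted amplitude of ≈4 local
noise SDs, the midpoint of the instrument's stated 3–5 sensitivity band.
mCherry defaults to a 0.04 s⁻¹ bleach rate so that, with event onsets
uniform over a 51 s series, roughly one third of second-channel traces
remain analyzable. The PSF is an anisotropic Gaussian, σ_xy = 110 nm,
σ_z = 380 nm, rasterised by voxel integration (error-function
differences).

## The recruitment-event generator

One event is: an abrupt onset at `round(Normal(burst_mean, burst_sd)/q)·q`
molecules (q = 1 for ESCRT-III, 6 for Vps4 — hexamers), a zero-drift
birth–death exchange process (Poisson arrivals balanced by binomial
departures of equal mean, in units of q), and a single-frame all-or-none
release. Lifetimes are drawn from `w·Exp(τ₁) + (1−w)·Exp(τ₂)` resampled
into [3, 45] s; defaults w = 0.7, τ₁ = 4 s, τ₂ = 20 s. Channel defaults:
Snf7 bursts of 60 ± 15 tagged molecules with a 40 s⁻¹ exchange rate
(fluctuations over an event's life become comparable to the mean, as the
traces this emulates show), Vps24 14 ± 3 at 6 s⁻¹, Vps4 20 ± 5 at
1.5 s⁻¹ in steps of six.

Scenes place class I emitters (diffusing at 0.05 µm²/s by default,
reflecting at the cell boundary, one event per channel) and class II
clusters: static objects (position jitter 12 nm SD) whose count series
sums 3–5 asynchronous, back-to-back event streams, so their totals are
3–5× a single event while fluctuating by single-event magnitudes. A
coupled second channel is generated as
`q·round((ratio·source + noise)/q)`, which correlates with the source at
lag zero by construction. Calibration fields emulate purified eGFP on
glass: sparse immobile emitters (70/20/10% monomer/dimer/trimer by
default), low background (0.02 photons·voxel⁻¹·ms⁻¹), single-step
photobleaching at 0.25 per frame.

**What the generator does not emulate:** spatially varying or
vesicle-shaped background, true ESCRT-III filament geometry (emitters are
ideal points), chromatic offsets between channels, stage drift, detector
fixed-pattern noise, or the full EMCCD gain cascade. Tests passing on
these scenes establish that the analysis chain is internally correct and
calibrated under its stated noise model — not that it is robust to every
artifact of a real instrument.

## Detection

Candidates are local maxima of the negated Laplacian-of-Gaussian response
at the PSF scale, thresholded at 4 robust SDs (MAD-based) of the response —
well below the ≈10 SDs a 3-molecule spot produces — plus a 10⁻⁴-of-maximum
floor that only matters on noise-free input. Candidates within 1.5 PSF σ
of the volume border are not fitted.

Spot fitting is two-stage. Stage one fits amplitude, sub-voxel position
and a constant local background with the Gaussian widths *fixed at the
PSF* — the matched-filter estimate. Stage two refines (σ_xy, σ_z) around
that solution purely as a shape descriptor for the diffraction-limited /
extended distinction. Quantification always uses the stage-one amplitude:
a free-width joint fit latches onto single-voxel noise spikes at low SNR,
inflating dim amplitudes by tens of percent and defeating the
significance test. Parameter SDs come from `inv(JᵀJ)·s²` of the stage-one
fit.

Acceptance combines the one-sided t-test `t = A/SD(A)` with
`dof = window voxels − 5` at α = 0.05, and a sensitivity floor
`A ≥ 2 × residual noise SD`. The floor is required because candidates are
*selected* local maxima: a pure-noise maximum passes the t-test almost
surely, but its matched-filter amplitude stays below ≈1.7 noise SDs while
a 3-eGFP spot sits at ≈3.7. Duplicate accepted fits within one PSF σ
(ellipsoidal distance) are merged keeping the higher amplitude. Degenerate
zero-variance residual windows accept iff A > 0.

## Tracking and validity

Per frame, active track ends and detections are matched by the Hungarian
algorithm on squared displacement, gated at 800 nm per elapsed frame
(diffusive class I motion at 850 ms spacing), with birth/death costs at
the gate; ends survive ≤2 missing frames (gaps are linearly interpolated
later and flagged). Ambiguity flags: competition of two ends for one
detection (or one end for two detections) within the gate marks the
involved tracks `merged`/`split`, as does an actual termination into an
assigned detection or a new track seeded inside an existing track's gate.

Valid tracks never merge or split, start after the first and end before
the last frame, contain only significance-accepted spots, keep **every**
position ≥1.5 µm from every volume edge (applied per spot, stricter than
a centroid rule, because it is unambiguous), and span ≥3 frames (the
shortest reportable lifetimes are ≈3 s ≈ 3–4 frames). Tracks present in
every frame are routed to a separate persistent set — their lifetimes
exceed the series and are excluded from lifetime fits but retained for
fluctuation analysis. Classification: diffraction-limited (median fitted
σ_xy within 1.3× PSF) and mobile (mean step ≥100 nm/frame) → class I;
extended, or static and ≥3× the class-I median intensity → class II;
dim static diffraction-limited objects stay unclassified.

## Calibration

Accepted amplitudes from the calibration field are fit by EM to the
constrained mixture `Σ w_k N(k·μ₁, k·σ₁²)`, K = 1..4 chosen by BIC. The
constraint encodes that k independent fluorophores emit k-fold the signal
with k-fold the shot variance, and it stabilizes EM on overlapping
components; the M-step has closed forms
(`μ₁ = Σ r_ik x_i / Σ r_ik k`, `σ₁² = Σ r_ik (x_i − kμ₁)²/k / n`).
`SD(μ₁)` comes from the observed information (numeric second derivative
of the log-likelihood in μ₁ at the MLE).

The field is imaged at 3× the cell-movie exposure and the fitted unit is
rescaled linearly back. At 21 ms a single eGFP yields only ≈2.4 peak
photoelectrons, where EMCCD gain quantization skews the amplitude
distribution and biases the Gaussian-mixture unit by ≈+8%; at 63 ms the
recovery is within ≈2.5%. Linear rescaling across exposures is the
calibration-curve contract (`unit_at(exposure)`).

Conversion: `N = A/μ₁` with
`σ_N = sqrt((σ_A/μ₁)² + (A·σ_μ₁/μ₁²)²)`; N is left non-integer and
negative amplitudes keep their sign (baseline noise must average to
zero). Hexamer counts are `round(N/6)` with half rounding up. The ×3
Snf7 factor (tagged subunits interspersed with two untagged copies) is a
configuration constant applied only on request, never baked into reported
tagged counts.

## Trace statistics

Lifetime = occupied frames × frame interval. The bi-exponential fit
maximizes the left-truncated likelihood
`f(t)/S(t₀)` for `t ≥ t₀ = min_observable` via Nelder–Mead in
(logit w, log τ₁, log τ₂) from three starts; CIs by percentile bootstrap.
Fits with |τ₂ − τ₁| ≤ 5% are reported as collapsed (single-exponential).
Maximum-accumulation modes use an unconstrained Gaussian mixture
(scikit-learn EM, 8 starts, tol 10⁻⁷ — looser tolerances leave a visible
first-mode bias) with the component count ≤K chosen by BIC, so unimodal
samples are not split; the lowest-mean component is the reported mode.
Cohorts group uncensored traces by lifetime into [3,5), [5,10), [10,51) s
bins (configurable — the bins are a presentation choice), align at onset,
and average with a percentile-bootstrap 95% band; cohorts under 10 traces
are dropped and logged. Cross-correlation is the per-pair Pearson
coefficient at each lag over the overlap window (positive lag = second
channel delayed), for mean-subtracted intensities and their first
differences, averaged over pairs with lifetime ≥11 s. Fluctuation peaks
use topographic prominence (≥6 molecules — one hexamer — for Vps4, ≥10
for Snf7, both configurable). An event is productive iff
`round(max_t N_t / 6) ≥ 4`. FRAP fits normalize to the first frame,
optionally divide out a reference-region exponential, locate the bleach
frame at the largest single-frame drop, and fit
`I(t) = plateau − (plateau − I_b)·e^{−kt}`; traces whose recovery
amplitude is within twice the frame-to-frame noise are flagged
`no_recovery`.

## Statistical utilities

The permutation test enumerates all C(n, n_x) group assignments when
feasible (p is then exact, the fraction of arrangements at least as
extreme including the observed one); otherwise it samples with the
add-one estimator `(1 + #extreme)/(n_perm + 1)`, which respects
`p ≥ 1/(n_perm+1)`. KS p-values are asymptotic by default (sample sizes
in this setting run to thousands), with the exact small-sample option
behind a flag. Bootstrap intervals are percentile intervals; constant
input returns a zero-width interval.

## Problem sizes

Tests and the acceptance script run the full-scale optics and noise model
on reduced fields of view — 48–96 px laterally and 10–16 planes, single
emitters or a handful per scene — and on generator-level populations of
2 000–25 000 events; the default 512×512×30 geometry remains available
as configuration. The acceptance script draws 5 000 mixture samples per
seed across five seeds, quantifies one 60-frame rendered bead-like
emitter per seed against a 300-spot calibration field, and renders 200
3-fluorophore spots for the sensitivity check.

## Known limitations

- The EMCCD model is the scaled-Poisson approximation; at ≪1
  photoelectron per voxel its discreteness departs from a Gaussian enough
  to bias mixture fits (hence the 3× calibration exposure).
- Amplitude quantification assumes diffraction-limited emitters; class II
  cluster amplitudes are matched-filter projections, not integrated
  intensities, and underestimate extended objects.
- The tracker links greedily frame by frame (optimal per frame, not over
  the whole movie); dense scenes relative to the 800 nm gate are flagged
  and rejected rather than disentangled.
- The truncated bi-exponential fit treats the 45 s upper clamp of the
  generator as negligible censoring; for series shorter than ~20 frames
  most events are right-censored and the fit is not attempted.
- Cross-correlation SDs are across-pair dispersions, not standard errors
  of the mean.
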