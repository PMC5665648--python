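# escrtdyn

Quantitative analysis of ESCRT-III and Vps4 recruitment dynamics on yeast
endosomes from lattice light-sheet (LLSM) movies — and a synthetic-data
generator that makes every stage of that analysis testable without any
microscope data.

The ESCRT machinery buds vesicles *into* endosomes: ESCRT-III filaments
(Snf7, Vps24, ...) assemble on the limiting membrane and the AAA+ ATPase
Vps4, acting as hexamers, remodels them until the vesicle pinches off.
Live-cell LLSM resolves these events as diffraction-limited spots that
appear abruptly, fluctuate, and vanish within 3–45 s. Turning those movies
into molecule-number statements requires a chain of quantitative steps,
all implemented here as a reusable Python library:

- **`synthetic`** — ground-truth recruitment events (abrupt ~60-molecule
  Snf7 bursts, Vps4 steps in multiples of six, bi-exponential lifetimes),
  diffusing class I emitters and static perivacuolar class II clusters,
  plus FRAP and calibration fixtures.
- **`render`** — a forward imaging model: voxel-integrated anisotropic
  Gaussian PSF, per-plane stage-scan shear, photobleaching, EMCCD
  excess-noise camera counts.
- **`volume_prep`** — flat-field correction, deskew of raw stage-scan
  stacks (500 nm stage steps → 261 nm z-steps at the 31.5° sheet angle),
  optional Richardson–Lucy deconvolution for visualization.
- **`detection`** — LoG candidates, 3D Gaussian fits with sub-voxel
  positions and amplitude uncertainties, a one-sided t-test of amplitude
  against local background.
- **`tracking`** — globally optimal frame-to-frame assignment, gap
  closing, merge/split flags, the valid-track filters (lifetime fully in
  the series, ≥1.5 µm from the volume border), class I/II assignment.
- **`calibration`** — the single-eGFP intensity unit from a constrained
  Gaussian-mixture fit (component *k* has mean *k·μ₁*, variance *k·σ₁²*);
  conversion `N = A/μ₁` with propagated error
  `σ_N = sqrt((σ_A/μ₁)² + (A·σ_μ₁/μ₁²)²)`; hexamer quantization
  (`round(N/6)`); the ×3 Snf7 tagging factor.
- **`trace_analysis`** — molecule-number traces, lifetimes and truncated
  bi-exponential maximum-likelihood fits, maximum-accumulation mixture
  modes, lifetime cohorts, two-channel cross-correlation, fluctuation
  peaks, the productive-event rule (≥4 Vps4 hexamers at any one time),
  FRAP recovery fits.
- **`stats`** — two-sample KS, exact/Monte-Carlo permutation tests,
  percentile bootstrap intervals.
- **`pipeline` / `escrtdyn` CLI** — `simulate | prep | detect | track |
  calibrate | analyze | report | all`, each stage reading the previous
  stage's artifacts from a run directory.

## Worked example

`examples/` holds one short narrative script per capability. For instance,
`python examples/04_trace_statistics.py` simulates 2000 Vps4-like
recruitment events and recomputes their summary statistics:

```
lifetime fit: w=0.53, tau1=2.9 s, tau2=10.8 s (n=2000)
maximum accumulation: first mode 30.9 +- 11.1 molecules (~5.2 hexamers, K=2)
productive events (>= 4 hexamers at some time): 85%
```

The lifetime fit describes the clamped (3–45 s) bi-exponential law the
generator draws from; the first mixture mode is where the bulk of events
peak in molecule content; the productive fraction counts events that ever
hold at least four Vps4 hexamers — the threshold associated with completed
intraluminal vesicles.

`python examples/03_single_molecule_calibration.py` builds a synthetic
coverslip calibration field and prints the fitted single-eGFP unit:

```
single-eGFP unit intensity: 127.5 +- 0.7 counts at 21 ms exposure (mixture K=3, n=541 spots)
a spot of 2500 +- 150 counts is 19.6 +- 1.2 molecules
as Vps4 that would be 3 hexamers; as tagged Snf7 it would imply ~59 total Snf7
```

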