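# Methods

This note documents the models, defaults and numerical choices behind
`pharmfc`, and what the synthetic validation does and does not show
about real data.

## Study design encoded in the defaults

The package targets mid-scan drug-challenge resting-state fMRI. The
default design, shared by the simulator and the analysis defaults, is an
80-min continuous acquisition at TR = 1 s (4800 samples), a vehicle
injection at 1200 s and a drug injection at 3000 s, two genotypes
(responder WT, non-responder KO) with 7 animals each, and 30 atlas-style
parcels. Runs are segmented into consecutive 10-min intervals — 2
baseline, 3 vehicle, 3 drug — and sliding-window dynamic FC uses a 300-s
rectangular window stepped by one TR.

**Window-count convention.** With `n_t` samples and window length `W`,
the stack holds `n_windows = (n_t - W) // step` matrices (4500 for the
default run). The inclusive convention would give one more window; the
adopted count is the one this family of designs reports, and the final
sample is the only one not covered by a window start.

## Synthetic cohort generator

### Latent factor model

Each animal's ROI signals are built as

```
x_i(t) = a f_{b(i)}(t) + c g(t) + Σ_e s_e(i) sqrt(|δ_e(t)|) u_e(t) + r_i(t) ε_i(t)
```

with block (community) factors `f_b`, a global factor `g`, edge-specific
factors `u_e` shared by exactly the two ROIs of edge `e` (sign pattern
`s_e` chosen so the edge covariance equals the signed `δ_e(t)`), and
private noise `ε_i`, all iid standard normal in time. Loadings satisfy
`a² = r_within − r_between`, `c² = r_between`, and the private-noise
loading `r_i(t)` absorbs the remainder so the stochastic core has unit
variance at every sample. Because the covariance is a Gram matrix of
loadings at each instant, the time-varying covariance path is positive
semidefinite by construction — no per-window Cholesky or projection is
needed — and the pairwise correlation of a modulated edge is exactly
`base_ij + δ_e(t)`. Configurations whose per-ROI budget
`a² + c² + Σ_e |δ_e|` exceeds 1 at any time are rejected as non-PSD.

Defaults: 4 communities of sizes 8/8/7/7, `r_within = 0.25`,
`r_between = 0.04`.

### Drug effect and envelope

Drug-modulated edges exist in WT only. Their delta follows a
pharmacokinetic envelope: a saturating exponential rise with time
constant τ = 120 s, peak (normalized to 1) at exactly 3τ = 6 min after
injection, then an exact exponential decay `2^(−s/T½)` with
T½ = 780 s — the ~13-min half-life of the modelled hormone. The piecewise
form makes two properties exact and testable: the envelope is zero
before onset and halves every T½ after the peak.

**Effect sizes.** The per-edge correlation deltas (|δ| = 0.68–0.75,
six increases and two decreases) were set by an analytic power
calculation for the paired drug contrast, not taken from any empirical
source: with n = 7, df = 6, 600-sample intervals band-limited to
0.008–0.1 Hz (effective Fisher-z SD ≈ 0.13 per animal for the
three-interval contrast) and BH correction over all 435 edges at
q = 0.01, per-edge deltas of this size yield ≈ 0.9 power. Two features
of that calculation shaped the defaults: the Fisher transform amplifies
a fixed correlation shift much more on edges with a non-trivial baseline
correlation, so modulated edges are placed within communities; and a
fixed-δ decrease from a positive baseline crosses zero where `atanh` is
flat, so decreases are intrinsically harder to detect and get the
largest |δ|. These are *calibrated-for-discoverability* synthetic
effects; they say nothing about physiological effect sizes.

### Injection artifacts

After **each** injection, in **both** genotypes: (i) a brief global
amplitude transient (multiplicative, amplitude 0.5, 40-s decay,
truncated at 120 s) — note that a pure amplitude modulation leaves
Pearson correlations unchanged, so this perturbs variance and spectra
without biasing FC; and (ii) three artifact edges shifted by +0.55 for
exactly one 10-min interval. The artifact edges are the targets of the
exclusion rule: they reach significance in both the drug contrast and
the mirrored vehicle contrast with the same direction, and must be
flagged. They are also placed within communities, because flagging
requires passing the mirror contrast's own BH threshold (only 3 true
edges among 435).

### Oscillators and band gains

Slow-band activity is modelled as independent narrow-band Gaussian noise
(2nd-order Butterworth band-pass around 0.02 Hz, ±0.007 Hz) added to a
three-ROI "network" with amplitude 0.35, and a gain table mapping
(genotype, condition) to an amplitude factor — by default ×2 in the WT
drug condition, i.e. ×4 in slow-5 power. Oscillators are added **on
top** of the unit-variance core rather than renormalized into it, so the
drug-condition amplitude increase is visible as a time-course SD change
(as an amplitude analysis expects); the cost is a small variance-driven
attenuation of correlations on oscillator ROIs, which the ground-truth
object accounts for analytically (`baseline_corr`,
`correlation_timecourse`). Per-ROI oscillator streams are independent,
so no spurious covariance is introduced.

### Nuisance, noise, randomness

Per-ROI polynomial drift (order 1, coefficient SD 0.8 over the run) and
two smooth pseudo-WM/CSF series with per-ROI loadings (SD 0.25) are
added and returned as nuisance regressors; spike noise and extra white
sensor noise are available but default to zero (sensor noise attenuates
all correlations by 1/(1+σ²) and is left off so ground-truth
correlations stay exact). One root seed spawns per-animal child streams;
each stream feeds both genotypes, so the KO cohort is bit-identical to
WT whenever no genotype-conditional effect is configured — cohorts are
also extensible without resampling existing animals. No hemodynamic
convolution is applied by default; an optional Gaussian smoothing kernel
can emulate it, but the analyses here operate below 0.1 Hz where its
effect is minor, and the white-spectrum core keeps the Fisher-z
sampling theory that the tests rely on exact.

## Preprocessing

Order fixed as detrend → nuisance regression → band-pass. Detrending and
regression share one least-squares projection (polynomial trend columns
plus nuisance columns; collinear columns dropped via pivoted QR with a
logged warning), so the filter cannot re-introduce removed drift. The
band-pass is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`, zero phase) in 0.008–0.1 Hz; zero phase matters because
windowed correlations would otherwise be shifted in time. The filtered
series is re-centred (edge transients leave a ~1e-2 DC residue
otherwise). Repeated application is not exactly idempotent — the
monotone Butterworth passband attenuates near-edge frequencies again on
a second pass (~14% RMS change, per-ROI correlation > 0.98); tests
assert this bounded contraction rather than strict idempotence.

## Statistics

- **Fisher z**: `atanh` with |r| clamped at 1 − 1e-7 (logged); group
  matrices are averaged in z-space and inverse-transformed only for
  display. NaN edges (constant ROIs) propagate and are excluded
  pairwise from group means with a logged count.
- **FC variability**: the population variance (ddof = 0) of the
  off-diagonal upper-triangle z values pooled over a condition's
  intervals, one scalar per animal; genotype comparison by two-sample t
  (df = n₁+n₂−2). This operationalizes "spread of edge strengths within
  a condition"; an alternative (variance across sliding windows) is a
  documented non-default reading.
- **Paired t**: `t = mean/(sd/√n)`, df = n−1, two-sided; all-zero
  differences give t = 0, p = 1; zero variance with non-zero mean is
  flagged degenerate (p → 0) rather than silently infinite.
- **FDR**: Benjamini–Hochberg step-up (statsmodels backend, verified
  against a hand step-up oracle); NaN p-values are excluded and returned
  as NaN. Edge discovery defaults to q = 0.01; q = 0.05 is exposed as a
  secondary threshold rather than silently resolving the two conventions.
- **Artifact exclusion**: an edge is an injection artifact if significant
  in both the drug contrast and the mirrored vehicle contrast (first
  post-vehicle interval vs mean of terminal baseline and vehicle
  intervals) *with matching direction* — an edge moving opposite ways
  after the two injections is not an artifact (conservative choice).
  The mirror construction itself is a design decision: it is the exact
  symmetric counterpart of the drug contrast.
- **Welch PSD**: Hann taper, 256-s segments, 50% overlap (resolves
  0.01 Hz while averaging ≥ 13 segments per 30-min condition series);
  series shorter than a segment fall back to a single segment with a
  warning. Band powers integrate the density by trapezoid with the band
  edges interpolated onto the frequency grid, so adjacent bands tile
  additively.
- **Group ICA**: temporal concatenation across animals, whitening to
  `n_comp` dimensions, FastICA (logcosh negentropy, fixed seed);
  components ranked by explained variance (squared mixing-column norm),
  maps unit-normalized with the largest-|value| feature made positive,
  per-animal time courses recovered by slicing the concatenated sources.
  Component "meaningfulness" is decided automatically instead of
  visually: a component is excluded if its time course correlates > 0.6
  with a nuisance regressor or > 50% of its map energy sits in one
  feature. Amplitude = within-condition SD (RMS exposed as an option).

## Problem sizes used in validation

The validation experiments run at the full default design (14 animals ×
30 ROIs × 4800 samples). Error control uses 200 independent stationary
null cohorts at 32 ROIs (496 edges, the closest edge count to 500
attainable with an integer parcel count); the recovery experiment uses
20 independent cohorts; ICA recovery uses a 3-source, 8-feature
mixture of 2000-sample Laplace sources. These sizes make the whole
suite and the acceptance script each complete in a few minutes on one
CPU while keeping Monte-Carlo standard errors small relative to the
margins being tested.

## Degenerate inputs and tie-breaks

Constant ROIs → NaN correlations (warned); |r| → 1 → clamped before
atanh; rank-deficient nuisance → collinear columns dropped (warned);
`n_comp` above data rank → reduced (warned); window length ≥ series →
error; condition spans not divisible by the interval length → error (no
partial intervals); the sample acquired at an injection instant belongs
to the post-injection interval (half-open, 0-based ranges). Export
row order for edge tables is ROI-label lexicographic; CSV floats use a
fixed format, so identical config + seed reproduce bundles byte for
byte.

## What passing tests do and do not show

The generator shares the analysis pipeline's *assumptions* (Gaussian
signals, stationary-within-condition covariance except for the injected
effects, linear nuisance). Passing recovery therefore demonstrates the
pipeline's internal correctness — bookkeeping, statistics, error
control, direction handling, artifact exclusion — under its own model.
It does not demonstrate robustness to what real BOLD adds:
non-Gaussianity, heavy-tailed motion artifacts, spatially correlated
physiological noise, hemodynamic convolution, inter-animal effect-size
heterogeneity, or registration error. Effect sizes are calibrated for
statistical discoverability at n = 7, which is larger in correlation
units than typical pharmacological FC effects; with realistic effect
sizes this design would be underpowered at FDR 0.01, which is a property
of the experimental design, not of the implementation.

## Known limitations

- The generator has no genotype-specific *baseline* connectivity knob;
  genotype baseline contrasts are exercised by simulating two cohorts
  with different community strengths.
- The FC-variability metric moves only mildly under the default
  injection artifact (3 of 435 edges shift), so condition-level
  variability differences are validated by paired with/without-artifact
  simulation rather than asserted as a large effect.
- Volume export writes float32 NIfTI (round-trip tolerance ~1e-3 in
  absolute signal units at the default scale); tables round-trip at
  1e-6.
- ICA on ROI-level features with few animals can fail FastICA
  convergence for high `n_comp`; the pipeline warns and results remain
  deterministic for a fixed seed.
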