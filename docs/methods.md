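# Methods

This note documents the model implemented by `fcloo`, the choices made where
the design was genuinely open, and what the synthetic-cohort tests do and do
not establish about real data.

## The classification model

The unit of data is a subject's symmetric R×R matrix of Fisher-transformed
Pearson correlations between ROI time courses; a *connection* is an unordered
ROI pair (i, j), i < j, enumerated lexicographically (the order of
`numpy.triu_indices(R, 1)`). Classification is leave-one-out: every quantity
used to score subject *s* is computed from the other n−1 subjects; *s*'s own
connectivity values enter only as the `x` being scored.

For held-out subject *s* and connection *c*:

1. **Site harmonization.** Every subject's value is adjusted by their site's
   mean for that connection, computed over the *remaining* subjects only, and
   re-centered on the remaining grand mean:
   `v ← v − mean_site(remaining) + mean_all(remaining)`. A site represented
   only by the held-out subject gets offset 0.
2. **Dual-group GLM.** `x ~ 1 + age + age² + gender + handedness` is fit by
   least squares separately to the remaining autism and control subjects
   (gender: female indicator; handedness: left and ambidextrous indicators,
   right as reference). Both fits are evaluated at *s*'s covariates, giving
   estimates x̂ₐ and x̂꜀.
3. **F-weighted score.** `s_c = (|x − x̂꜀| − |x − x̂ₐ|) · F` with `F = t²`
   from the pooled two-sample t between the remaining groups. The order of
   the absolute differences is fixed by the sign convention: proximity to the
   autism estimate must push the score positive.
4. **ROI aggregation.** For each ROI, average `s_c` over its incident
   connections in the active subset (ROIs with none contribute 0); the
   classification score S is the sum of the R per-ROI averages. S > 0
   predicts autism.

Connection subsets are: all connections; `{c : p_c < α}` recomputed for every
held-out subject from the remaining subjects' t-tests (α ∈ {0.01, 0.001,
10⁻⁴, 10⁻⁵}); or a strength-by-distance bin. Under subsets, the per-ROI
average divides by the number of incident *selected* connections (the
all-connections rule is the R−1 special case).

### Why harmonization is applied to the data, not the estimates

Two algebraically similar site adjustments exist. The *estimate-shift* form
fits the GLMs on raw values and then adds the offset
`mean_site(remaining) − mean_other_sites` to both estimates. The
*harmonization* form (our default, `site_adjust="harmonize"`) removes the
same per-site means from the data before any fitting or testing.

Harmonization has two decisive properties, both covered by tests:

* **Exact shift invariance.** Adding a constant to every matrix of one site
  changes every harmonized value by one *global* constant, which the GLM
  intercepts absorb exactly; t statistics, selections, and scores are
  unchanged to round-off (measured ≤ 1e−13 relative). Under the
  estimate-shift form the group fits themselves move by roughly
  (n_site-in-group / n_group)·k, so the cancellation is only approximate.
* **Null calibration.** On null cohorts (no group effect) the estimate-shift
  form is systematically *optimistic*: the held-out subject's own group at
  their own site is underrepresented by one in the site mean, creating a
  small group-identifying covariance between the offset and the group
  estimates that accumulates over ~F-weighted connections. Harmonization is
  mean-unbiased. The estimate-shift variant remains available as
  `site_adjust="estimates"`; `site_offset()` implements the offset itself.

One side effect to know: because harmonization subtracts *estimated* site
means, within-site values become weakly negatively correlated, and the
per-connection t-test is slightly liberal on multisite data (a p<0.01
selection keeps somewhat more than 1% of null connections). The selection
test calibrates exactly on single-site data, where no adjustment is applied.

### Degenerate cases and numerics

* Rank-deficient covariate columns (e.g. a single-gender group) are dropped
  greedily left-to-right and recorded; dropped columns contribute 0 to
  predictions. A group smaller than retained-columns + 2 falls back to its
  mean, flagged degenerate.
* Zero pooled variance makes t undefined: the connection is flagged, given
  F = 0 and p = 1, and never selected.
* An empty selected subset yields score 0, the majority label of the
  remaining subjects, and a flag.
* The vectorized engine (`per_connection_loo`) computes each held-out
  subject's scores with shared per-group least-squares solves across all
  connections; a naive per-connection loop reference reproduces it to ~1e−11
  relative (tested at R ≤ 20, n ≤ 40).

## Evaluation layer

Scores are thresholded at 0 or at the ROC point maximizing sensitivity +
specificity (Youden J), ties broken toward the smaller threshold (a threshold
cannot change the area under the curve, so the Youden point is the coherent
reading of "ROC-optimized"). Accuracy significance is the exact one-sided
binomial tail P(X ≥ k | n, ½) via the regularized incomplete beta; for
n = 964 the 0.05 and 0.001 boundaries are 509 (52.8%) and 531 (55.1%)
correct. Correlation p-values use the t transform on n−2 df, pairwise
complete over subjects with the measure present; multiple comparisons use
Benjamini–Hochberg. `per_roi_accuracy` reports a display floor — the binomial
critical fraction at level q, i.e. the step-up boundary if all R regions
shared one p-value — as its FDR-style reference line.

## Preprocessing

* **Temporal filter**: one orthogonal projection onto (band-limited subspace
  for 0.001–0.1 Hz at the given TR) ∩ (linear-trend-free subspace): linear
  detrend, ideal FFT mask, then removal of the trend components that survive
  inside the passband. Projection form makes the filter exactly idempotent
  and output means exactly zero; passband gain at 0.05 Hz (TR = 2 s) is
  ≥ 0.999 and stopband gain at 0.2 Hz ≤ 0.03.
* **Nuisance regression**: least-squares residualization on regressors +
  intercept; rank-deficient sets are handled by a minimum-norm solve with a
  warning (residuals are identical to column-dropping).
* **Framewise displacement**: root-mean-square of the six frame-to-frame
  rigid-body parameter differences, rotations converted to arc length at a
  50 mm radius — following the "root-mean-square displacement" wording; the
  other common convention (L1 sum) is available via `mode="l1"`. FD[0] = 0.
* **DVARS**: RMS temporal difference across channels, divided by the series'
  global standard deviation by default so that one numeric threshold can be
  applied to FD (mm) and DVARS (signal units) together. This shared-threshold
  design is inherently under-specified: on smooth band-limited data,
  sd-scaled DVARS sits around 0.3–1, so a 0.2 threshold flags above-typical
  signal change rather than rare spikes. The scale is a knob (`scale=` a
  float, `"sd"`, or `None` for raw units); calibrate it to your data, or
  scrub on FD alone as the cohort generator does.
* **Scrubbing**: frames with FD or DVARS above threshold (default 0.2), plus
  one neighbor on each side, are removed and survivors concatenated;
  idempotent by construction; removing every frame is an error that reports
  the zero retained count.

## The synthetic cohort generator

`simulate_cohort(SimParams)` emulates the statistical structure a multisite
connectivity classifier must cope with. Connection value of subject *s* at
connection *c*:

```
z_sc = baseline_c + β_age·age_s + β_age²·age_s² + u(site_s, c)
       + severity_s · δ · 1[c ∈ affected] + ε_sc
```

with `u(site, c) ~ N(0, σ_site²)` drawn once per site×connection,
`severity_s = |N(1, 0.3²)|` for autism subjects and 0 for controls, and
`ε_sc ~ N(0, σ_e² + 1/(T_ret,s − 3))`. The second variance term is the
asymptotic sampling variance of a Fisher-z correlation estimated from
`T_ret` retained volumes — the generator's stand-in for finite scan length
(toggle `scan_length_noise`), with `T_ret` obtained by actually simulating a
motion trace per subject and scrubbing it at 0.2 mm. Behavioral scores are
linear maps of severity plus noise whose intercepts, slopes and noise scales
anchor the group means near typical clinical values (SRS ≈ 21 vs ≈ 92, ADOS
≈ 1.3 vs ≈ 11.9, verbal IQ ≈ 112 vs ≈ 105, Vineland ≈ 105 vs ≈ 75; ADI-R
only in the autism group). All randomness descends from one seed through
`numpy.random.SeedSequence` spawning.

Defaults describe one small multisite study, chosen once: R = 100 lattice
ROIs (4950 connections), 5 sites × 12 subjects (6/6 per diagnosis), 150
volumes at TR = 2 s, effect_fraction = 0.02, δ = 0.5 z, σ_site = 0.1,
σ_e = 0.2, ages uniform 6–60, 85% male, handedness 86/12/1% R/L/A,
motion spike rate 0.05/volume. `simulate_timeseries` inverts a Fisher-z
matrix to correlation scale (diagonal load up to 0.1, then unit-diagonal
rescale; harder targets are rejected) and draws i.i.d. multivariate-normal
volumes, so empirical matrices converge to their target at the 1/√(T−3)
rate — used to validate the connectivity layer against known structure.

What the generator does **not** emulate: autocorrelated BOLD spectra, spatial
covariance between connections (values are independent given the planted
structure), scanner physics or susceptibility artifact, site differences in
anything but additive offsets and scan length, and missing behavioral data
beyond the ADI-R pattern. Passing tests therefore show the *pipeline
mechanics* are right (hygiene, invariances, calibration under the stated
model, recovery of planted effects), not that real cohorts of this size would
classify at these accuracies.

## Calibration findings worth knowing

Measured on this generator and reproduced by the test suite and
`scripts/acceptance.py`:

* With no planted effect the classifier's mean accuracy is at chance, but its
  *spread across cohorts* exceeds the binomial noise of n independent
  predictions: LOO scores share their training data, and the F = t²
  weighting lets chance-extreme connections move all of a cohort's scores
  coherently. At n = 120 the 95% binomial band around 50% captures roughly
  three quarters of null cohorts rather than 95%; the excess dissipates by
  n ≈ 240. Significance claims for a *single* cohort's accuracy at these
  sizes should therefore not lean on the binomial reference alone.
* Scan length matters through estimation noise: with σ_e small, per-subject
  measurement noise scales as 1/√(T−3), and site-level accuracy rises with
  volumes acquired. The direction is reproducible when the analysis has
  site-level degrees of freedom (the shipped analysis uses 15 sites spanning
  50–300 volumes, site accuracy averaged over the four p-value selection
  thresholds at ROC thresholds); with ~5 sites the correlation sign is close
  to a coin flip.
* Accuracy saturates quickly in δ: with 2% of connections affected, planted
  effects ≥ 0.25 z classify nearly perfectly at n = 120, so studies of
  accuracy *gradients* (effect size, scan length) must sit at small δ.

## Known limitations

* The classifier is the classical F-weighted deviation scheme; no regularized
  or machine-learning alternatives, and no network-level graph metrics.
* NIfTI/image-space preprocessing (realignment, normalization, segmentation)
  is out of scope: inputs are ROI-level series or precomputed matrices.
* The handedness imputation feature space (standardized age + one-hot gender
  and site, k = 5, Euclidean, ties to the majority class) is a documented
  choice; the convention it replaces is not specified anywhere.
* Strength/distance bin edges anchor at 0 by default; the anchor is
  configurable because the canonical choice is not fixed by convention.
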