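# Methods

This package implements connectome-based predictive modeling (CPM) of a
behavioral trait from source-space EEG phase-locking networks, together
with the synthetic-data machinery needed to validate every stage against
a known ground truth. This note documents the models, the defaults and
why they were chosen, what the generators do and do not emulate, and the
numerical conventions.

## The predictive model

For each subject, functional connectivity is a symmetric ROI × ROI
matrix of phase-locking values (PLV) in one frequency band; its strict
upper triangle (row-major, diagonal excluded) is the feature vector —
n(n−1)/2 edges, 2278 for the 68-region Desikan–Killiany parcellation.
The CPM stages are:

1. **Edge z-transform.** Each edge is standardized with the mean and
   *sample* SD (n−1 denominator) across the **training** subjects of the
   current fold; held-out subjects reuse the training parameters.
   Edges with zero training SD are masked and contribute z = 0
   everywhere.
2. **Edge selection.** Each standardized edge is Pearson-correlated with
   the behavior score; edges with two-sided p < α (default α = 0.01,
   via t = r·√((n−2)/(1−r²)) on n−2 df) form the positive ("high") and
   negative ("low") tails. Selection is invariant to per-edge affine
   maps with positive scale, so selecting before or after the
   z-transform gives identical tails.
3. **Summary index.** Per subject, Σ = (sum of positive-tail z) −
   (sum of negative-tail z) in combined mode; single-tail modes use one
   sum. Empty tails contribute 0 and set a degenerate flag.
4. **SVR.** An ε-insensitive support vector regression with RBF kernel
   relates Σ to the score. Defaults: C = 1, ε = 0.1, kernel bandwidth
   1/(n_features × feature variance) resolved to a number at fit time.
   These are conventional values (the feature is one-dimensional, so
   the fit is cheap and insensitive to C over a wide range); all are
   configurable and recorded in the model bundle.
5. **Validation.** Leave-one-out (one fold per subject) or seeded
   k-fold (near-equal random folds, no stratification — scores are
   continuous). Metrics are computed on predictions **pooled** across
   folds: with singleton LOO test sets a per-fold correlation does not
   exist. For k-fold the fold-averaged r is additionally reported.
   Reported metrics: Pearson r with its parametric two-sided p, MAE,
   and both R² conventions — r² (`r2_sq`) and 1 − SSres/SStot
   (`r2_ss`, primary; the two differ for miscalibrated predictions).

**Permutation test.** Each of n_perm (default 5000) iterations applies
one full random permutation to the score vector and reruns the entire
cross-validated pipeline, including per-fold re-selection. The p value
is the literal counting fraction #(r_null ≥ r_observed)/n_perm, which
can be exactly 0; the (b+1)/(n+1) estimator is available as an option.

**Degenerate folds.** When a fold selects no edges, its SVR sees a
constant zero feature and predicts a per-fold constant. The pooled
metrics are still computed from these actual predictions (the report is
flagged `degenerate` and its parametric p set to NaN when *no* fold ever
selects an edge). Substituting a fixed r for degenerate runs would bias
the permutation null: a fully degenerate LOO run's pooled r is a
deterministic, typically strongly negative function of the score
multiset (leaving out a high scorer drags the training set's central
value down), and an arbitrary replacement value would rank incorrectly
among permutations.

**Consensus networks and external transfer.** An edge enters the final
network if selected in ≥ 90% of folds (per tail; the threshold is
inclusive). The frozen model refits standardization and the SVR on the
full internal cohort restricted to the consensus edges — per-fold models
differ slightly and no single one is canonical, so the deterministic
refit is used. External cohorts are standardized with the internal
cohort's parameters, never their own; external behavior scores are
max-normalized within the external cohort (reconciling heterogeneous
scoring scales). Bundle predictions are evaluated from the stored
support vectors in plain numpy, so a serialize/deserialize round trip
(JSON; doubles survive via shortest round-trip repr) is bit-identical.

**Dynamic variant.** The sliding-window PLV trajectory (all epochs
concatenated) is reduced to a per-edge temporal variance σ² (sample
variance, n−1), and the identical CPM code path runs on the variance
matrix.

## Connectivity

- **Band definitions:** delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
  gamma 30–45 Hz.
- **Filtering:** zero-phase (forward–backward) Hamming-window FIR
  band-pass; transition width 10% of the lower band edge, tap count
  capped at (n_samples−2)/3 so the filtfilt padding stays valid on
  short epochs.
- **Phase:** analytic signal (Hilbert transform) per epoch, so
  transients never leak across epoch boundaries.
- **Windows:** default length 6 cycles of the band's center frequency,
  non-overlapping; windows never straddle epochs. Window length and
  step are recorded in the output container; an option can trim the
  first/last window of each epoch (off by default).
- **Diagonal convention:** stored as 1 in static matrices (0 in
  variance matrices), never exported as a feature.

## Synthetic cohorts

The real cohorts (two resting-state EEG datasets, n = 90 and n = 41,
with a real-life creativity inventory) are available only on request, so
all validation runs on generated data emulating that regime.

- **Behavior.** Creative-activity and creative-achievement scores are
  lognormal (right-skewed, like real-life creativity inventories whose
  totals span roughly 1–472); the total is exactly their sum. Default
  log-SDs are 0.5/0.6: moderate skew keeps a 90-subject cohort's
  standardized trait within a few SD — heavier tails put single
  subjects at 5–8 SD, which pushes planted edge weights into the [0,1]
  clip and destabilizes every downstream estimate. Covariates: age
  ~ N(39.6, 12.7²) clipped to [18, 68]; gender 0/1 with p(1) = 2/3;
  education ordinal 0–5 — all generated independently of the scores.
  Max-normalization divides each score column by its within-cohort
  maximum.
- **Connectomes.** Edge weight = baseline (0.5) + per-subject global
  offset (SD 0.1) ± β·trait on planted edges + N(0, noise_sd²) noise,
  clipped to [0,1] (clipping is logged; < 0.1% of weights at default
  settings). The global offset emulates overall coupling-level
  differences between subjects (vigilance, anatomy, recording quality).
  It loads equally on both tails and cancels exactly in the combined
  (positive − negative) index, which is what makes the combined model
  robustly outperform either single tail — the qualitative structure the
  pipeline is meant to exhibit. It also correlates all null edges, so
  the p < 0.01 consensus screen yields far fewer false discoveries than
  an independent-edges calculation would suggest.
- **Time series.** Each ROI gets unit-variance band-limited Gaussian
  noise; each planted pair mixes in a shared band-limited oscillation
  with proportion a (a = 1 ⇒ identical signals ⇒ PLV 1). Static mode:
  a = baseline ± β·trait. Dynamic mode: a oscillates between the same
  two levels for every subject, but the switching frequency is
  trait-dependent (β in octaves per trait SD around a 0.6 Hz center).
  Slow switchers hold coupling states across analysis windows (high
  window-to-window PLV variance); fast switchers average the states out
  within windows. An amplitude-in-trait modulation was rejected: PLV is
  nonlinear in a, so both the variance *and the static mean* scale with
  amplitude², and the "dynamic-only" signal leaks into the static
  connectome. The switching-rate mechanism still leaves a small static
  footprint (windows containing a switch have downward-biased PLV), so
  a per-subject trait-independent baseline-coupling jitter (SD 0.14)
  swamps the residual mean signal while barely touching the variance
  signal.
- **Seeding.** Every generator derives one child stream per subject from
  the master seed via `SeedSequence.spawn`, with a distinct domain tag
  per generator. Consequences: identical seeds reproduce cohorts
  bit-for-bit; enlarging a cohort preserves existing subjects; and the
  behavior and connectome generators remain independent even when
  handed the same master seed (without the domain tags the "random"
  subject offsets would be deterministically coupled to the scores).
- **Not emulated:** sensor artifacts, volume conduction/leakage,
  1/f spectra, inter-regional anatomy, the inventory's item structure.
  Passing tests show the *pipeline* recovers planted structure under
  its own assumptions; they say nothing about effect sizes in real EEG.

## Source reconstruction (toy)

The inverse kernel is the depth-weighted minimum-norm estimate
K = W⁻²Lᵀ(LW⁻²Lᵀ + λI)⁻¹ with W = diag(‖L·ᵢ‖^γ). Defaults γ = 1 and
λ = trace(LW⁻²Lᵀ)/(9·n_sensors) (the usual 1/SNR² heuristic at SNR 3).
ROI series are per-sample means of member sources (no sign flips — the
toy lead field has no orientations). There is no head geometry, noise
covariance, or electrode registration; the stage exists so the full
sensor → source → connectome → CPM chain is executable and testable.

## Validation scales and frozen thresholds

Simulation-based checks run at reduced scales chosen once, from
simulations performed before the corresponding thresholds were frozen:

- **Null calibration** (permutation-p uniformity): 200 replicate null
  cohorts, n = 30, 10 ROIs (45 edges), LOOCV, 99 permutations, with
  independent edges (global offset off) and selection α scaled to 0.1.
  The α scaling keeps the expected null selection count (4.5 edges) in
  the non-degenerate operating regime of the full-scale pipeline
  (at 2278 edges and α = 0.01, ~23 null edges pass in every run);
  at α = 0.01 with 45 edges most runs select nothing, and fully
  degenerate runs all produce the same pooled r, putting an atom in the
  null that no valid p estimator can smooth away.
- **Signal recovery:** n = 90, 10 ROIs, 5+5 planted edges, β = 0.2,
  noise SD 0.02; thresholds recall ≥ 0.8, FDP ≤ 0.2, combined pooled
  r ≥ 0.8, combined ≥ each single tail. Verified on 10 consecutive
  seeds before freezing (combined won 10/10 with ~0.1 margins).
  The full 68-ROI scale runs in `analysis/04`.
- **External transfer:** frozen bundle applied to a 41-subject cohort
  from the same generative process; null transfer (permuted external
  scores over 100 fresh cohorts) rejects at ≈ 5%.
- **Dynamic pathway:** n = 48, 16 ROIs, fs 250 Hz, 2 × 20 s epochs,
  gamma band, 0.5 s windows, effect 1.1 octaves/SD; thresholds
  dynamic recall ≥ 0.6, static recall ≤ 1/3 (12/12 seeds pre-freeze:
  dynamic 0.67–1.0, static ≤ 1/3). Full study scale (68 ROIs,
  3 × 40 s at 1 kHz, n = 90) would require ~6 GB of raw series per
  cohort; the reduced scale preserves the windows-per-modulation-cycle
  and cycles-per-window regime.

## Known limitations

- The SVR stage is the pipeline's noise floor: with a near-noiseless
  summary index, pooled LOOCV r saturates around 0.95–0.98, not 1.0,
  because the ε-tube (0.1 on scores in [0, 1]) tolerates deviations.
- The p < 0.01 edge screen controls per-edge error, not FDR; the number
  of consensus false discoveries depends on the null-edge dependence
  structure, so recovery thresholds are meaningful only at their stated
  generator settings.
- Fully degenerate cross-validation runs report an artifact-driven
  (typically negative) pooled r with a NaN parametric p; interpret the
  permutation p instead in sparse-selection regimes.
- The toy forward/inverse stage makes no claim of anatomical realism.
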