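# Methods

## Model and procedure

The package implements connectome-based predictive modeling for a
continuous score. The unit of analysis is a subject's symmetric node × node
matrix of Fisher-z-transformed Pearson correlations between parcel time
courses; edges are addressed as 0-based upper-triangle pairs (i, j), i < j,
in row-major order, so edge files are reproducible across runs and tools.

Per leave-one-out fold: Spearman correlation of every edge with the score
over the n−1 training subjects; edges with two-sided p < 0.05 split by the
sign of ρ into positive and negative predictive networks; per-tail network
strength as the sum of Fisher-z weights over the selected edges; an OLS
line from strength to score; prediction of the held-out subject from its
own strength. Model performance is the Spearman correlation of
cross-validated predictions with observed scores, and inference is by
re-running the whole nested procedure on score-shuffled data. Spearman
rather than Pearson selection is used because clinical severity scores are
typically non-normal; strengths are summed on the z scale (a switch to
back-transformed r would be a one-line change in `network_strength`, but z
is the scale the matrices are built on).

Assumptions worth stating: the strength model is univariate and linear, so
it captures only the aggregate monotone association of the selected
network; the two tails are modeled and evaluated separately, not combined
into one regression; covariates are screened (`covariate_screen`) but not
regressed out of edges or scores.

## Numerical and procedural choices

- **Spearman p-values** use the t-distribution approximation with average
  ranks for ties (df = n−2). Exact per-edge permutation p-values are
  infeasible at ~36k edges × n folds. For a fixed training size the
  approximation's p is strictly monotone in |ρ|, so the p < threshold rule
  is applied internally as an equivalent critical value on |ρ|; this is
  what makes the batched permutation test (one matrix product per fold for
  all shuffles) exact, not approximate, relative to the per-edge rule.
- **Threshold comparisons are strict**: p < 0.05 selects, FD > 0.5 mm
  scrubs, rotation > 2° / translation > 2 mm / mean FD > 0.15 mm excludes.
  A value exactly at a threshold is kept.
- **Fisher transform clipping**: r is clipped to ±(1 − 1e−7) before
  arctanh, so perfect correlations give z ≈ ±8.4 instead of ±∞.
- **Zero-variance nodes** yield z = 0 on all their edges with a logged
  warning; the subject is retained so the cohort stays aligned.
- **Empty-selection folds** (no edge passes the screen in a tail) predict
  the training-set mean score; this keeps LOOCV defined and is logged. A
  constant prediction vector is scored ρ = 0 inside cross-validation, since
  it carries no ordering information.
- **Constant strengths** in a fold trigger the same mean-score fallback
  (slope 0).
- **Permutation p** is one-sided toward positive ρ, estimated as
  (k+1)/(n_perm+1); its floor at 1,000 shuffles is 1/1001. Only scores are
  shuffled; matrices (and any covariates) keep their order.
- **Cleaning order** is detrend → nuisance regression → band-pass
  (zero-phase 2nd-order Butterworth, applied forward–backward). The
  narrative order of such pipelines is often ambiguous; each step can be
  disabled independently. Mean FD for the exclusion rule is computed on the
  unscrubbed trace. With node-level synthetic data there is no voxelwise
  global signal; the mean across nodes is the documented stand-in when
  global-signal regression is wanted.
- **Degree ties** in the top-k node report are broken by ascending node
  index and flagged in a `tied` column.
- **Comparator hyperparameters**: linear kernel, C = 1, within-fold
  standardization for both SVR (LOOCV, CPM-selected edges pooled across
  tails as features) and SVM (stratified 10-fold on all upper-triangle
  edges, pooled out-of-fold sensitivity/specificity, balanced accuracy as
  their mean, mean |w| per edge across folds for interpretation). The
  protocols are underspecified in the literature this follows; these
  defaults are deliberate, documented assumptions, not tuned values.
- **Threading**: `--threads` parallelizes permutation folds; shuffles are
  generated up front from the seed, so threaded and serial results are
  identical.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the analysis needs and
nothing more. Scores are drawn from a normal distribution truncated to
[3, 95] whose parent location/scale are solved (via the truncated-normal
moment equations) so the *truncated* law has mean 40.1 and SD 22.3 — the
severity-score distribution of the modeled cohort; truncation without this
calibration would bias the mean upward by ≈1.9 points. An optional skewness
parameter is exposed because such scores are typically non-normal, but no
particular shape is asserted by default.

A planted edge's weight is `0.3 + 0.15·(e·s + √(1−e²)·ε)` with s the
standardized score, ε standard normal, and e the effect size, so the
population edge–score Pearson correlation is exactly e (sign-flipped for
negative edges). All other edges are score-independent draws from
Normal(0.3, 0.15²) in z units — plausible resting-state connectivity
magnitudes, configurable. The time-series generator instead couples planted
node pairs through a shared latent signal whose mixing weight is
score-scaled (subject-level target correlation r₀ + 0.25·e·s around
r₀ = tanh(0.3), clipped to ±0.95), which exercises the full
time-course → connectome path; it also emits a synthetic framewise-
displacement trace with a configurable spike fraction above the 0.5 mm
scrubbing threshold. All randomness descends from one seed through a
splittable `SeedSequence`, so per-subject draws are order-independent and
runs are bit-reproducible.

What the generator does **not** emulate: spatial structure and smoothness,
hemodynamics, scanner noise and physiological artifacts, the dependence
structure among non-planted edges (they are independent, real connectomes
are not), site or motion confounding of the score. Passing tests therefore
demonstrate that the *procedure* is correct and calibrated — selection,
cross-validation, permutation inference, recovery of planted effects — not
that any particular real dataset would yield a given prediction accuracy.

The shipped default atlas is a synthetic block assignment that reproduces
the published node counts of the ten macroscale regions of the 268-node
parcellation (prefrontal 46, cerebellum 41, temporal 39, limbic 36,
parietal 27, occipital 25, motor 21, subcortical 17, brainstem 9, insula 7)
and splits nodes nearly evenly over the eight canonical network labels; the
true node-level assignment is not public as a table, so any real analysis
should supply its own atlas TSV.

## Validation design and observed behavior

Three behaviors of the nested procedure that the test suite pins down are
worth knowing about when interpreting results:

- **Fold-intersection networks are not false-positive-free.** LOOCV folds
  share n−2 subjects, so a null edge whose full-sample p is well below the
  threshold (≈2% of edges at a 0.05 screen) tends to survive *every* fold.
  The contributing network's precision therefore depends on how many null
  candidate edges compete: with tens of candidate edges per planted one,
  precision drops well below 1 even at large effect sizes. Recovery tests
  use dense planted networks (20 of 105 edges) where precision ≥ 0.9 is
  attainable; recall of strongly coupled edges is essentially perfect.
- **Strength-sum dilution.** Chance-selected edges enter the strength sum
  with full weight, so single-edge effects predict well only when the
  candidate pool is small; prediction accuracy rises with the planted
  fraction of the network, not only with the effect size.
- **LOOCV mean-fallback bias.** When a fold predicts the training mean,
  that prediction is perfectly antitone in the held-out score, pushing null
  ρ negative. The CPM engine at realistic edge counts is centered near
  zero (every fold selects something), but the SVR comparator at very small
  edge counts shows the effect strongly; the permutation test remains
  calibrated regardless, because the null statistics carry the same bias.

The leakage guard demonstrates the complementary failure: selecting edges
on the full cohort before cross-validating only the linear fit inflates
null ρ to ≈0.65 on 60-subject null cohorts, while the nested procedure
stays at ≈0. `loocv_fixed_selection` exists only to make this comparison.

## Problem sizes

Simulation-based tests run at reduced but statistically adequate sizes:
null calibration at 120 subjects × 50 nodes × 199 shuffles × 50 replicates;
recovery at 200 subjects × 15 nodes × 20 seeds; leakage at 60 × 30 × 20.
The acceptance script uses 122 subjects × 100 nodes × 1,000 shuffles. The
batched permutation engine (precomputable per-fold edge ranks; one GEMM per
fold over all shuffles) keeps a full 1,000-shuffle test on that problem
under a minute on one CPU; 268-node cohorts are supported and simply scale
the same computation.

## Known limitations

- k-fold cross-validation is provided (`kfold_cv`) but the validated
  protocol is leave-one-out; no covariate-adjusted (partial-correlation)
  edge selection; no regularized CPM variants.
- The negative tail's permutation test uses the same one-sided
  (ρ ≥ observed) direction as the positive tail.
- Image-level preprocessing (slice timing, realignment, normalization,
  smoothing, parcellation) is out of scope; the pipeline starts at node
  time series or connectivity matrices.
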