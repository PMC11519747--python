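# Methods

## Data model

A cohort is `N` subjects × `E` edges of Fisher-z functional connectivity
plus one trait score per subject. Node ids are 1-based (matching how atlas
tables number ROIs); edge ids are 0-based, enumerating the strict upper
triangle row-major, so `E = P(P−1)/2` (35,778 for the 268-node reference
layout). `compute_connectome` builds the matrix from a `T × P` ROI
time-series table as `atanh(Pearson r)` per ROI pair; plain Pearson is used
with no autocorrelation correction. Correlations with `|r| = 1` are clipped
to `1 − 1e−7` (with a warning) so features stay finite rather than failing.
Matrices read from disk must be symmetric within `1e−6` — within tolerance
they are averaged with their transpose, beyond it the file is rejected as
wrong data rather than float noise.

The bundled 268-node atlas (`ctcpm.atlas.shen268_synthetic`) reproduces the
reference macroscale layout exactly — prefrontal 46, motor 21, insula 7,
parietal 27, temporal 39, occipital 25, limbic 36, cerebellum 41,
subcortical 17, brainstem 9 — but its MNI coordinates and network sublabels
are synthetic, generated deterministically; it supports structural and
aggregation logic, not anatomical lookup.

## Selection

**Screen.** Edge-wise Pearson correlation with the trait across subjects;
two-tailed p from the t distribution with `N−2` df; pass at `p < alpha`
(default 0.01). A constant edge gets `r = 0, p = 1` and can never pass; a
constant trait is an error. The association sign of an edge is fixed here,
from the full-cohort `sign(r)`.

**Collinearity pruning.** The collinearity criterion uses `|r| ≥ 0.8`:
anti-correlated near-duplicates are as redundant as correlated ones.
Grouping is greedy and deterministic: features are visited in descending
MI-with-trait order (ties to the lower edge id) and accepted iff their
absolute correlation with every already-accepted feature is below the
threshold. Given distinct MI values this realizes "keep the highest-MI
member of each collinear group" independent of input order.

**MI estimator.** Both variables are discretized into `n_bins = 8`
equal-frequency bins via average ranks (`ceil(rank · B / n)`), then the
plug-in discrete MI in nats. Rank-based binning makes the estimate exactly
invariant under strictly monotone transforms (up to ties, which share a
rank and hence a bin). Eight bins mirror the quantile treatment of the
target in the stratification step; since MI is only used for ranking, the
log base is immaterial. The plug-in estimator's positive bias
(≈ (B²−1)/2n nats) is shared by all features at fixed `n`, so rankings are
unaffected by the bias itself, but its variance at small `n` is why
consensus selection needs a clear signal to be stable (see "Simulation
regimes").

**Consensus.** For each of the `K·R` training portions (fresh seeded K-fold
partition per repeat; defaults K = 6, R = 4) features are ranked by MI
computed on the training subjects only; the consensus set is the
intersection of every ranking's top `ceil(0.6 · F)` features. The top
fraction is taken of the pruned feature count `F`, rounded up. With fewer
than two pruned features the consensus is the pruned set itself.

## Prediction

The trait is quantile-binned (8 equal-frequency bins by average rank; bins
emptied by heavy ties trigger automatic bin-count reduction with a warning)
and subjects are dealt round-robin into 10 folds within each bin, with the
dealing offset carried across bins so overall fold sizes also differ by at
most one. Each fold's model is OLS with intercept — an intercept is always
included because the scores are not centered — and no regularization; a
rank-deficient or underdetermined design raises an error instructing to
tighten selection instead of silently regularizing. This matters at study
scale: a consensus set comparable to the sample size (e.g. ~189 edges
against ~140 training rows) cannot be fit by honest OLS, so the packaged
model stage refuses it. Standard errors are textbook
`sqrt(diag(σ̂²(XᵀX)⁻¹))`, `σ̂² = RSS/(n−k−1)`; an exact fit (RSS ≈ 0 at
relative tolerance 1e−12) yields `se = 0` and a signed infinite t sentinel
with a warning, which propagates through importance averaging.

Two evaluation summaries are reported and labeled separately because they
differ: fold-wise MAE/RMSE/R² averaged (± SD) across folds, and the pooled
out-of-fold predictions' Pearson r and `R² = 1 − SSE/SST`.

**Nested mode.** By default, selection runs once on the full cohort before
model cross-validation (the reference pipeline order), which leaks test
information into selection and inflates CV estimates on null data.
`nested=True` re-runs the entire screen→prune→consensus inside each
training fold and predicts the held-out fold with that fold's own features;
on signal-free cohorts its pooled r centers at zero while the default mode's
does not (both are measured in the acceptance suite). Nested per-fold
feature sets differ, so per-edge importance is undefined there; the network
summary always derives from the full-cohort selection.

## Network summary

Edge importance is the across-fold mean t-statistic. The top-k report ranks
by `|mean t|` (a signed ranking is available by flag) with ties to the lower
edge id, since the selected network mixes positive and negative
associations. Node degree is computed on the consensus network only.
Macroscale count matrices are 10×10 symmetric; within-region edges sit on
the diagonal counted once, so each matrix's upper-triangle-plus-diagonal
total equals its edge count and the positive and negative totals partition
the consensus set.

## Synthetic cohorts

`simulate_cohort` draws trait scores from a truncated normal (defaults:
mean 61.35, SD 10.81, range 40–92, n = 156, matching the motivating
sample's reported distribution; truncation is single-pass rather than
resampling, so the realized SD is the truncated distribution's, slightly
below the parent SD). Background edges are i.i.d. `N(0, 0.3)` in Fisher-z
units — 0.3 is a typical between-subject spread for resting-state Fisher-z
edges. Signal edges (default 88 positive + 101 negative, the reported
network's sign split) additionally receive `sign · β · z(score)`, additive
in Fisher-z space on the standardized score — the same linear form the
pipeline fits, which makes parameter recovery a fair test of the
implementation, not of model misspecification. One integer seed drives all
stage randomness through derived sub-seeds.

What the generator does **not** emulate: spatial autocorrelation between
edges sharing a node, subject-level global connectivity shifts, motion
confounds, non-Gaussian edge noise, or hemodynamic time-series structure.
Passing recovery tests therefore validates the algorithmic chain, not
robustness to real fMRI artifacts.

**Simulation regimes.** `beta_magnitude` spans weak to strong signal; the
population edge–trait correlation is `β/√(β² + σ²)`. The default β = 0.1
(r ≈ 0.32) is a moderate regime where single-edge screening has ~93% power
at n = 156 but the MI-ranking consensus is unstable — the 8-bin plug-in MI
noise at n ≈ 130 exceeds the MI separation between signal and chance-passing
edges, so the 24-ranking intersection keeps only a minority of true edges.
This is a faithful property of the method at that SNR. The strong regime
used for recovery testing is β = 0.3 (r ≈ 0.71, per-edge SNR 1), where the
full pipeline recovers essentially all planted edges with the correct signs.

## Problem sizes in the test and acceptance runs

Tests use desk-scale cohorts (P = 60, E = 1,770, n = 156) for full-pipeline
checks and P = 40 for calibration loops (200 screening cohorts, 50 nested
null pipelines); the acceptance script additionally runs the selection stage
at the full P = 268 (E = 35,778) scale. These sizes were chosen so the whole
suite completes in seconds-to-minutes while keeping n at the study's 156,
which is the quantity that drives every statistical property tested.

## Known limitations

- The model stage deliberately has no fallback for `k ≥ n_train − 1`
  (no ridge, no pinv); selection must be tightened instead.
- The plug-in MI estimator is biased and high-variance at small n; it is
  used for ranking only, and rankings are what the consensus consumes.
- Equal-frequency binning with heavy ties can reduce the effective bin
  count; the reduction is warned about, not silent.
- The bundled 268-node atlas is synthetic in its coordinates; real analyses
  should supply their parcellation's atlas CSV.
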