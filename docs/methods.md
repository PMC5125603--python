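# Methods

## Problem and model

`harhmm` classifies smartphone activity-recognition *feature windows*: each
window is a vector of p statistics (means, correlations, energies, ...)
summarising one fixed-width segment of accelerometer and gyroscope signal,
normalized channel-wise to [-1, 1] and labelled with one of six activities
(1 Walking, 2 Upstairs, 3 Downstairs, 4 Sitting, 5 Standing, 6 Laying).

Classification is hierarchical, coarse to fine to accurate:

```
                 all windows
               /            \
        moving {1,2,3}   stationary {4,5,6}
         /        \         /        \
   walking {1}  {2,3}   laying {6}  {4,5}
               /    \              /    \
        upstairs  downstairs  sitting  standing
```

Every decision node holds one continuous hidden Markov model (CHMM) per
branch. A window's (transformed) feature vector is reshaped into T =
ceil(p/O) frames of length O (the last frame zero-padded), and the branch
whose model assigns the sequence the highest forward log-likelihood wins:
r' = argmax_r log P(O | lambda^r). Ties break to the smallest activity code.

Each CHMM is lambda = (A, B, pi): Q hidden states with initial distribution
pi and transition matrix A, and per-state emission densities b_i(o) that are
M-component diagonal-covariance Gaussian mixtures over the O frame
coordinates. Likelihoods use a log-space forward recursion (log-sum-exp);
a classic scaled-forward implementation is kept as an internal cross-check
and the two agree to better than 1e-8. Training is Baum–Welch EM over the
node's training windows; the total log-likelihood is non-decreasing per
iteration and the fit stops at relative improvement < `em_tol` (default
1e-5) or `em_max_iter` (default 100) iterations.

## Per-node feature transforms

* **Stages 1–2 (root, moving, stationary): forest-selected subset.** A
  random forest (default ntree = 500, mtry = floor(sqrt(p))) is fit on the
  full six-class training set; features whose importance score is at or
  above the arithmetic mean of all scores are retained (ties at the mean are
  kept — the rule is "score >= mean", not ">"). Mean decrease in impurity is
  the default measure; permutation importance is available behind the
  `importance="permutation"` flag. Because forest importances are
  run-dependent, the seed is a required, logged parameter; repeated forests
  can be averaged via `n_repeats` (default 1, i.e. a single forest).
* **Stage 3, sitting vs standing: sparse locality preserving projection.**
  Row i of the affinity matrix W solves the nonnegative l1 reconstruction
  problem min_w ||x_i − X^T w||² + lambda ||w||₁ with w ≥ 0 and w_i = 0, so
  each sample's neighbourhood size is selected adaptively by the penalty
  rather than by a manual k. The graph is symmetrized as W ← (W + W^T)/2
  (standard graph-embedding practice; it preserves nonnegativity), and the
  embedding A solves the generalized eigenproblem X^T L X a = lambda X^T D X a
  (L = D − W), taking the d smallest informative eigenpairs with columns
  scaled so a^T (X^T D X + ridge·I) a = 1. The graph is built on the
  sitting+standing training rows of the forest-selected subset, and the
  fitted linear map is reused verbatim on test windows (the method is
  out-of-sample by construction). Default d = 13, clipped to the number of
  available columns.
* **Stage 3, upstairs vs downstairs: gyroscope channels only.** Stair
  direction is a rotation signature, so this node keeps exactly the features
  whose name contains the (configurable, case-sensitive) substring `"Gyro"`
  — taken from the *original* full feature space, not the forest subset.
  The `swap_stage3` flag exchanges the two stage-3 transforms for
  experimentation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `frame_len` (O) | 8 | coordinates per observation frame |
| `stage1_states/mix` | 4 / 2 | coarse-node CHMM size |
| `stage2_states/mix` | 4 / 3 | fine-node CHMM size |
| `stage3_states/mix` | 2 / 2 | accurate-node CHMM size (two states at this stage are part of the method) |
| `n_estimators` | 500 | forest size for importance scoring |
| `splpp_components` | 13 | sparse-LPP embedding dimension |
| `splpp_lambda` | 0.1 | l1 penalty on [-1,1]-scaled data |
| `splpp_ridge` | 1e-6 | trace-scaled ridge on X^T D X |
| `variance_floor` | 1e-3 | minimum emission variance on [-1,1] data |
| `em_max_iter`, `em_tol` | 100, 1e-5 | Baum–Welch stopping rule |

All values are exposed as estimator parameters and, for the CLI, through a
YAML config. The sparsity penalty `splpp_lambda` and the frame construction
(reshaping a window's feature vector into consecutive length-O frames) are
genuinely open design choices of this implementation: neither is pinned
down by the method description the package follows, and the reshaping in
particular is the largest interpretive decision — it makes every window
scorable as an independent short sequence.

## Numerical choices

* Emission covariances are diagonal; the variance floor (re-applied after
  every M-step) prevents collapsing components from producing unbounded
  likelihoods. Starved mixture components are re-seeded from a random frame
  with a warning.
* Initialization: uniform pi, A and mixture weights; means from seeded
  k-means with Q·M centroids over the pooled frames (perturbed global mean
  when there are fewer frames than centroids); variances start at the pooled
  per-dimension variance.
* The nonnegative-lasso rows are solved by coordinate descent (closed-form
  soft-threshold update per coordinate, tolerance 1e-8, at most 10^4
  sweeps); the test suite verifies the optima against a brute-force grid
  and against an independent solver.
* Generalized eigenvalues below 1e-10 (relative) are treated as degenerate
  directions and skipped when enough informative ones exist; requesting more
  dimensions than attainable is an error that states the attainable count.
* Determinism: one master seed is spawned (via `numpy` seed sequences) into
  per-node seeds, so identical data + seed gives identical selections,
  embeddings, EM traces and predictions.

## The synthetic corpus

`harhmm.synthetic` generates six-activity corpora with the statistical
structure the pipeline exploits, so every stage is exercisable without the
external smartphone dataset. Windows are sampled from per-class
Gaussian-mixture CHMMs (2 states, 2 mixtures) over 5 frames × 12 channels
(8 accelerometer-named, 4 gyroscope-named per frame; p = 60 columns
total), then min-max normalized to [-1, 1] per channel on the training rows
(test rows mapped with the training affine transform and clipped) and split
70/30 stratified by class. Defaults: 60 windows per class, separation 1.0,
emission sd 0.25 — chosen once as a small but realistically noisy corpus
whose class geometry mirrors the real problem.

By construction: moving and stationary classes are widely separated;
upstairs and downstairs share every accelerometer-channel parameter and
differ only in gyroscope channels (so accelerometer-only models sit at
chance on that pair while gyroscope-only models separate it); sitting and
standing differ only along one dense direction (so a linear embedding is
needed); laying is far from both; two accelerometer and two gyroscope
channels per frame are pure noise (so the forest selection is non-trivial).

What the generator does **not** emulate: subject heterogeneity, sensor
placement variation, the within-window correlation structure of real
time/frequency-domain statistics, class imbalance, and the real dataset's
561-feature dimensionality. Passing tests on this corpus therefore
demonstrate the pipeline's mechanics and its stage-wise rationale, not
field accuracy on real recordings; published accuracy figures for the real
smartphone dataset are reference behaviour reproducible only with that
dataset downloaded.

## Problem sizes

The default corpus (360 windows, 60 features) keeps a full train + evaluate
cycle at a few seconds; the parameter-recovery check uses 200 simulated
sequences of 50 frames; forward-algorithm exactness is checked against
exhaustive path enumeration at Q ≤ 3, T ≤ 6 where the enumeration is cheap.

## Known limitations

* The row-rate column of the confusion report is the row-normalized
  diagonal (per-class recall); some published tables label this same
  arithmetic "precision". The report names it `row_rate` to keep the
  arithmetic unambiguous.
* Viterbi decoding, full-covariance emissions and learned (non-fixed)
  hierarchies are out of scope; the pipeline needs only likelihoods and the
  fixed six-activity tree.
* With very small per-class sample counts the sparse graph can become
  disconnected and EM can starve components; both paths warn rather than
  fail, but accuracy degrades as expected.
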