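# Methods

`varicpm` implements a pipeline linking the temporal variability of regional
functional connectivity to recovery from depressive symptoms: variability
estimation from windowed resting-state and repeated task-condition fMRI,
self-construal-moderated and self-vs-other contrast features, a
leave-one-out cross-validated predictive procedure with permutation
inference, and a simple-effects moderation analysis — together with a
synthetic cohort generator that plants known effects so every stage is
testable without access to any real cohort.

## The variability statistic

For a node *k* and a collection of functional-connectivity (FC) matrices
indexed by *i* (windows of a resting scan, or repeated scans of one task
condition), the connectivity profile `F_{i,k}` is row *k* of matrix *i*
with the diagonal self-entry removed ("the remaining nodes").  The temporal
variability is

```
V_k = 1 - mean_{i<j} corr(F_{i,k}, F_{j,k})
```

with plain Pearson correlations: `V_k ∈ [0, 2]`, 0 iff the profile is
perfectly stable, 2 iff consecutive profiles anti-correlate.  No Fisher
z-transform is applied anywhere by default (the statistic operates on raw
coefficients); `fisher_z=True` is exposed as a sensitivity option.

Resting-state ("general") variability uses nine non-overlapping 30-s
windows: at TR 2 s with 150 acquired volumes and the first 5 discarded,
145 samples hold exactly nine 15-sample windows taken consecutively from
the first sample, the 10-sample remainder discarded.  Task
("self-referential") variability computes one FC matrix per scan from the
whole condition segment — no sub-windowing — and compares across the six
scans (C(6,2)=15 pairs).  Condition contrasts subtract mean variability
between condition groups (self minus other over the three domains, either
condition group minus the font control, or single-domain pairs).

**Estimation floor.** With 15-sample windows, each FC entry carries
sampling error of roughly `(1-r²)/√15`, which attenuates the
profile-profile correlations; measured V therefore has a floor around
0.8-0.9 at 264 nodes even when the generating covariance is bit-identical
in every window.  This is a property of the estimator (and of any real data
analyzed with it), not of the simulator: V = 0 is attainable only in the
degenerate identical-matrices case.  Between-participant differences in V
ride on top of that floor.

Degenerate inputs (a constant node signal within a window, a zero-variance
connectivity profile) are hard errors naming the offending node, never
silent NaNs.

## Behavioral scoring and features

Recovery is the baseline BDI minus the 3-month score (positive = less
depressive); interdependence is the interdependent-subscale mean minus the
independent-subscale mean of the Self-Construal Scale.  Baseline BDI ≥ 14
defines the high-depression group and ≤ 4 the low group; the printed group
ranges make both boundaries inclusive, and scores in (4, 14) are labeled
`none`.

The self-construal-dependent predictor at node *k* is the interaction
`X_k = z(V_k) · z(I)` (unbiased-SD z-scores across participants).  The
normalization scope is configurable:

* `training_fold` (default): within each LOOCV fold the z-statistics come
  from the 59 training participants and are applied unchanged to the
  held-out one — leakage-safe;
* `global`: cohort-wide normalization before the analysis.

Both are first-class because the original description ("before the
prediction analysis") suggests cohort-wide normalization while fold-wise
normalization is the defensible modern default; in simulation the two give
nearly identical operating characteristics.  The self-referential predictor
is the raw self-minus-other contrast of condition variability, not
normalized.

## The predictive procedure

Per LOOCV fold (each of the n participants held out exactly once):

1. **Selection** — two-sided Pearson test of each node's feature against
   recovery over the training rows; `p < α` (default 0.05, robustness
   setting 0.01, strict inequality) splits selected nodes by sign into
   positive and negative sets.
2. **Model establishment** — the positive-set features are averaged into
   the positive strength; the *negated* negative-set features into the
   negative strength; the total strength averages the two defined
   strengths (an equally valid count-weighted pooling of all signed
   features is available as `total_strategy="pooled"`).  Each strength is
   regressed on recovery by ordinary least squares — no regularization, no
   covariates.
3. **Prediction** — the held-out strengths (using the training fold's node
   sets and normalization statistics) are substituted into the fitted
   lines.
4. **Evaluation** — predictive power is the Pearson correlation between
   the n LOOCV predictions and observed recovery, with a parametric
   two-sided p reported alongside; "successful prediction" means r > 0 and
   p < 0.05.  A model with a no-feature fold is invalid (flagged with the
   count, never imputed).  Nodes selected in strictly more than 95% of
   iterations are the *important nodes*, sign-labeled by their mean
   training correlation over the folds that selected them.

**Permutation inference.**  Recovery is shuffled (seeded, independent of
the cohort seed) and the *entire* procedure — including per-fold
re-selection and re-normalization — is rerun; the empirical P is the
add-one estimator `(1 + #{null r ≥ observed r}) / (1 + #valid)`.
Permutations in which a model goes invalid are excluded from its valid
null but reported.  Two properties of this null are worth knowing:

* it is *wide* — at n = 60 with 264 weakly dependent features its SD is
  ≈ 0.2 and its 95th percentile ≈ 0.3, because features selected against
  the permuted outcome correlate with it by construction over the nearly
  identical folds.  The permutation test, not the parametric p of the
  LOOCV correlation, is therefore the inferential anchor;
* conditioning a single-sign model's null on validity (a nonempty set in
  every fold) makes that model's empirical P conservative.

The subgroup robustness check reruns LOOCV within each depression group
with the selection stage replaced by a fixed node set (e.g. the important
nodes), refitting the regression per fold; groups need ≥ 5 members.

## Moderation (simple effects)

`recovery = b0 + b1·V̄ + b2·Ic + b3·(V̄·Ic)` by OLS, where V̄ is the mean
important-node variability on its natural scale (slopes are per unit
variability) and Ic is interdependence mean-centered before the product is
formed (centering recomputed within any analyzed subgroup).  The simple
slope at interdependence `mean + c` is `b1 + b3·c` exactly, with
`SE² = Var(b1) + c²Var(b3) + 2c·Cov(b1, b3)` from the coefficient
covariance and two-sided t p-values on the residual degrees of freedom;
evaluated at c = ±SD.

## The synthetic cohort generator

The generator defines the study conditions: 60 participants; one 150-volume
resting scan at TR 2 s; six task scans, each with one 12-volume block per
condition (seven conditions: self/other × mental/physical/social, plus a
font control; 12 volumes ≈ 8 items × 3 s at TR 2 s); 264 nodes; a 28/32
high/low baseline-BDI split drawn from the published group distributions.

**Signal model.**  Signals are zero-mean multivariate normal.  Random
connectivity patterns are low-rank-plus-diagonal correlation matrices
(14 latent factors — the parcellation's network count — plus a 25%
idiosyncratic diagonal share), which keeps FC off-diagonals around 0.2 at
any matrix size, comparable to real connectomes; a full-rank draw would
shrink them like 1/√n and leave nothing measurable above the windowed-FC
sampling noise at 264 nodes.  Each window/block draws its covariance as a
per-node convex mixture of a fixed base correlation matrix `C0` (one per
participant) and a fresh random correlation matrix `R_w`:

```
C_w[k,l] = sqrt((1-w_k)(1-w_l))·C0[k,l] + sqrt(w_k·w_l)·R_w[k,l]
```

`w_k ∈ [0,1)` is node *k*'s variability target; the construction keeps
`C_w` a valid correlation matrix, `w = 0` reproduces `C0` exactly every
window, and measured V is monotone in the target in expectation (rank
correlation > 0.8 across a 10-level target ladder, averaged over seeds).
The generator's covariance-state period is aligned with the analysis
windows so the target has a clean interpretation as "fraction of the
node's connectivity pattern that reconfigures per window".

**Targets.**  Rest targets are `N(0.45, 0.15)` clipped to [0.02, 0.9] —
wide enough that between-participant differences in *measured* V clearly
exceed the windowed-FC estimation floor, reflecting that individual
differences in connectivity variability are reliable traits; effect nodes
additionally load on a participant-level common factor with correlation
`effect_node_correlation` (default 0.9), i.e. planted effects are
subnetwork-coherent rather than scattered over independent nodes.  (A
power argument makes coherence necessary, not just realistic: a composite
effect with population R² fixed and spread over K *independent* nodes gives
per-node feature-outcome correlations of `0.5/√K`, far too small for any
node to be selected in > 95% of folds.)  Task targets equal rest targets
shifted by ± half of a planted self-minus-other offset at the effect
nodes.

**Behavior.**  Interdependence is standard normal on the
subscale-difference scale.  Recovery is exactly

```
recovery = b_int · mean_k z(V_k)·z(I)  +  b_so · mean_k z(D_k)  +  ε
```

over the effect nodes (D = self-minus-other contrast, ε ~ N(0, noise_sd²),
default 2 BDI points), and every draw is recorded in a `GroundTruth` so
the planted model reconstructs recovery bit-exactly.  The variability
matrix fed to this stage may be either the generator's targets (fast
calibration studies) or measured V (full end-to-end runs).  Second-screen
BDI is stored as the exact real value `bdi_t1 - recovery`; the instrument's
integer 0-63 range is enforced only for real raw data (`strict=True` in
the scorer), since exact reconstructability and integer bounds cannot both
hold under Gaussian noise.  Group labels are assigned independently of the
planted effect by default (the published effects held in both groups); a
switch couples them.

All randomness flows from one master seed through a documented
stream-splitting rule (`SeedSequence(seed).spawn(3)`: targets, time
series, behavior); same seed + same spec ⇒ bit-identical cohort.

**What the generator does not emulate:** hemodynamics, scanner noise
(drift, spikes), spatial autocorrelation between node spheres, non-Gaussian
BOLD marginals, task-evoked mean responses, or volumetric images (node
space only; the NIfTI extraction path is validated against tiny constructed
volumes instead).  Passing tests therefore demonstrate correctness and
calibration of the *procedures*, not that real cohorts carry effects of the
planted kind.

## Problem sizes and numerical choices

Calibration studies run on target-level variability matrices (the
behavioral stage accepts them directly), which makes hundreds of replicate
cohorts tractable: null calibration uses 200 replicate null cohorts at the
full design size (n=60, 264 nodes) with 200 permutations each — the type-I
rate of the permutation test at α=.05 must land in [0.02, 0.09] and the
selection stage must pick ≈ 5% of nodes under the null; planted-effect
recovery uses 50 replicate cohorts with the composite-feature population
R² set to 0.25 analytically from the effect-node covariance structure.
The permutation engine is vectorized across permutations and proven
exactly equal (1e-12) to a per-permutation rerun; selection thresholds are
implemented as critical |r| values from the t quantile, avoiding per-node
p-value computation in inner loops.  Cholesky sampling adds a 1e-9 jitter
only if a mixture covariance is numerically semidefinite.  Ties at
p = α are not selected (strict inequality); importance uses strictly
greater than the 0.95 threshold.

## Known limitations

* The LOOCV predictive power is an optimistically biased estimate (fold
  selections share 58 of 59 training rows); only the permutation test
  corrects for this.  With the planted composite effect at population
  R² = 0.25 and n = 60, the joint event "r > 0.2 and empirical P < .05"
  occurs in ≈ 75-80% of replicate cohorts — the permutation null's width,
  not the estimator, is the limiting factor.
* Measured V compresses the target scale severely (estimation floor plus
  shallow response), so effects planted on targets are attenuated when
  expressed through measured variability; end-to-end demonstrations size
  the planted slope against the measured covariance instead.
* The atlas shipped for simulations is geometrically synthetic (random
  non-overlapping spheres; published 14-network proportions); analyses of
  real volumes should supply the real sphere table in the same TSV format.
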