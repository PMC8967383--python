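# Methods

`tntmvpa` implements a pattern-based analysis of retrieval suppression:
does actively suppressing the retrieval of an unwanted memory leave a
sustained mark on its neural representation, visible as reduced
reactivation and reinstatement after the suppression phase, and does
that neural change track the loss of subjective vividness? Because raw
MRI data for this paradigm are typically not shareable, the package
pairs the full analysis stack with a seeded generative model of the
experiment, so every stage can be validated against planted ground
truth.

## The simulated experiment

The generator reproduces a Think/No-Think design with three item
conditions (16 items each by default):

* **pre-test / post-test** — every item is cued once for 3 s and
  covertly recalled; a vividness rating on a 1–5 scale follows. The
  default inter-trial spacing is long (3 s trial + 3 s rating + 14 s
  ITI) so single-trial responses are separable.
* **Think/No-Think phase** — five blocks in which each *recall* and
  each *suppress* item appears twice for 3 s with truncated-exponential
  ITI jitter on [2, 8.5] s calibrated to a 3 s mean; *baseline* items
  are withheld entirely and control for the passage of time.
* **localizer** — twelve 16 s blocks (six per class) of intact versus
  morphed aversive scenes, with at most two same-class blocks in a row,
  used to train the scene decoder.

Voxel time series follow the forward model the analysis assumes. Each
trial contributes two additive components, both convolved with the
canonical double-gamma HRF: a *category* (scene) template scaled by a
per-(phase, condition) amplitude, and an *item-unique* template scaled
by the item amplitude. The category and item amplitudes sum to the
scalar trial amplitude that also drives the vividness ratings
(`rating = clip(round(a + b·amplitude + noise), 1, 5)`), so the neural
and behavioural effects share one ground truth. A per-subject effect
δ_i reduces the category amplitude of suppress items at post-test only;
in the multi-subject pipeline δ_i is drawn from a truncated normal, and
its population mean and spread are the knobs that set effect size and
brain–behaviour coupling. The two components are kept separate (rather
than a single template scaled by the summed amplitude) because
item-specific reinstatement is only recoverable if items carry signal
that the category template does not.

Noise is AR(1) Gaussian (default marginal SD 1, lag-1 coefficient 0.3)
plus low-frequency cosine drift and simulated nuisance regressors
(slow random walks standing in for motion/physiological confounds)
that leak into the data with small voxelwise loadings. Scene templates
are concentrated (3× loading SD) in the two PhC compartments of the
voxel space, so parahippocampal ROIs carry more category signal than
the rest of gray matter. The generator makes no attempt to model MRI
physics, head motion, or physiological recordings; defaults were chosen
once for testability at realistic effect magnitudes, not fitted to any
dataset.

## Single-trial estimation (LSS)

Trial patterns are estimated with the least-squares-single strategy:
one GLM per trial containing the target-trial regressor, a collapsed
all-other-trials regressor, the nuisance columns, a discrete-cosine
high-pass set with a 128 s cutoff (order `K = floor(2·T/cutoff)`), and
an intercept. For the Think/No-Think phase the target unit is the item
(all repetitions share one regressor); for the localizer it is the 16 s
block. Estimates are converted to voxelwise t-values via the
target-minus-others contrast at residual dof `T − rank(X)`. Boxcars are
built at dt = 0.1 s, convolved, scaled by dt (so the regressor
approximates the continuous convolution independently of grid
resolution) and sampled at the scan times with microtime onset 0.
Voxels with numerically zero residual variance get NaN t-values, which
propagate with pairwise exclusion (and a logged count) instead of
infinities. No spatial smoothing or AR prewhitening is applied
anywhere in the pattern path.

## Decoding and scene evidence

A linear SVM (C = 1, no feature scaling by default; both exposed) is
trained per ROI on the localizer block t-patterns, with the sign
convention that positive decision values indicate intact scenes.
Weights are converted to a forward-model activation pattern
`A = Cov(X)·w` (sample covariance of the training patterns). Scene
evidence for a trial is the dot product of the pattern with the trial's
t-map; within a subject every quantity derived from evidence is a
contrast, so the global scale of `A` is irrelevant there. The pipeline
additionally normalises the scoring template to unit L2 norm so that
reduction scores are on a common scale *across* subjects — without
this, between-subject variation in `‖A‖` acts as multiplicative noise
on the brain–behaviour correlation while leaving all within-subject
statistics unchanged.

Cross-validation scores every block exactly once while held out, so
accuracy is a multiple of 1/12. The default fold scheme holds out one
block of *each* class per fold, keeping training class-balanced; the
classical leave-one-block-out variant (train on 11 of 12) is available
as `scheme="loo"` but is not the default because its imbalanced
training fold biases a margin classifier against the held-out class —
on pure-noise patterns the 11-of-12 scheme's expected accuracy is
roughly 0.44 rather than 0.5 at this sample size, which would make
every chance-level sanity check misleading.

A second calibration caveat is documented rather than fixed: block
patterns estimated from a single run are temporally anticorrelated
(HRF overlap between closely spaced blocks makes neighbouring estimates
compete for shared variance), and the ≤2-in-a-row ordering constraint
correlates class labels with temporal adjacency. Null decoding through
the full GLM path is therefore slightly above chance even with a
balanced scheme — a genuine property of closely spaced block designs,
not of the decoder. Calibration checks of the decoder itself are run on
pattern-level nulls.

## Reinstatement (RSA)

For each hemisphere's PhC, every pre-test item pattern is correlated
(Pearson, over ROI voxels, pairwise-excluding NaN voxels) with every
post-test item pattern. Similarities are Fisher-z transformed (r
clipped at 1 − 1e-7, clip events logged — noiseless synthetic fixtures
do reach the boundary). Per item, `z_same` is the diagonal entry and
`z_diff` averages the same-condition off-diagonal entries in the
pre(i)×post(j) direction (a symmetric variant averaging both directions
is available); restricting the different-item pool to the same
condition means condition-level mean shifts cannot masquerade as
item-specific reinstatement. Per condition and subject the
reinstatement index is `R = z_same − z_diff`, and the
suppression-induced reduction is `R_baseline − R_suppress`.

## Group statistics

* **Reduction scores** (vividness, evidence per ROI):
  `(pre_suppress − post_suppress) − (pre_baseline − post_baseline)`.
* **Within-subject factorial ANOVA** for two-level factors, computed by
  the balanced Möbius (marginal-means) decomposition; each effect's F
  equals the squared one-sample t of its orthogonal subject-level
  contrast, with df (1, n−1) — exact for two-level within factors, so
  no sphericity correction is needed. Effect sizes are generalized eta
  squared, `SS_effect / (SS_effect + SS_subjects + ΣSS_error)`. The
  implementation is cross-checked in the tests against a brute-force
  sums-of-squares oracle and against pingouin.
* **t-tests**: paired and one-sample, two-sided, with Cohen's d defined
  as `mean(diff)/sd(diff)`; a zero-variance sample with nonzero mean
  yields t = ±inf with a logged warning (p = 0) rather than a silent
  NaN. `summary_t_vs_chance` computes the same test from a published
  (mean, SD, n) accuracy summary.
* **Trialwise evidence–vividness test**: per-subject Pearson r over
  pre-test trials → Fisher z → group one-sample t against zero;
  zero-variance subjects are excluded with a report.
* **Skipped Spearman correlation**: robust bivariate centre by
  fast-MCD (h = floor((n+3)/2) support points, seeded); outliers are
  points whose projection onto any observation's direction from the
  centre exceeds sqrt(χ²₀.₉₇₅(2)) robust SDs (1.4826·MAD) from the
  projection median; Spearman (midranks) on the survivors; 95%
  percentile-bootstrap CI over seeded resamples of the survivors only
  (the outlier step is not re-run inside the bootstrap, default 1000
  resamples). The procedure is invariant to translation, common
  rescaling and axis sign flips, but *not* to anisotropic affine maps —
  the projection directions do not transform covariantly — and under
  clean bivariate normality the union-over-projections rule flags a few
  percent of points; both properties are inherent to the standard rule.

No multiple-testing correction is applied, and all p-values are
two-sided.

## Pipeline, determinism and problem sizes

`run_experiment` executes simulate → GLM → decode → RSA → stats for N
subjects. Subject seeds derive from `SeedSequence([master_seed, 7919,
subject_index])`, so a single subject can be re-simulated independently
of batch order; every stochastic step (noise, jitter, MCD, bootstrap)
descends from these seeds and reruns are byte-identical, which the
manifest (config, seeds, SHA-256 per artifact) makes checkable. The
`calibrate` harness repeats reduced experiments over a grid of planted
δ values and reports detection rate of the time×condition interaction,
the mean estimated reduction, and the correlation between planted δ_i
and estimated per-subject reductions.

Monte-Carlo validation runs use deliberately reduced problem sizes —
4 items per condition, 32 voxels over three compartments, shortened
test ITIs and a 3+3-block localizer — chosen so that hundreds of full
pipeline replicates are cheap while every stage remains statistically
non-trivial; the brain–behaviour coupling scenario uses the full 16
items and 48 voxels because the correlation of two noisy reduction
scores is the most measurement-hungry quantity in the pipeline.

## What passing tests do and do not show

The generator's noise is stationary AR(1) with linear nuisance leakage
and its templates are exactly stable across phases; real data add scan
artefacts, motion-correlated signal, representational drift, and ROI
missegmentation. Passing recovery and calibration checks therefore
demonstrates that the estimators and statistics are implemented
correctly and are well-calibrated under the assumed generative model —
not that the paradigm's effects would be detectable at these sample
sizes in real recordings.
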