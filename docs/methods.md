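# Methods

## Estimand and estimator

The target is the average causal effect on the risk-difference scale,
ACE = E[Y(1) − Y(0)], for a binary exposure Z and binary outcome Y with
pre-exposure covariates X. Identification assumes consistency,
exchangeability given X, and positivity; the package estimates, it does not
adjudicate those assumptions — covariate selection (excluding mediators,
colliders and instruments) remains the analyst's task, and the simulators
never generate mediators or colliders.

The estimator is standardization with a fitted Q-model f(Y | Z, X): predict
Ŷᵢ(1) and Ŷᵢ(0) per subject by overriding the exposure column (and every
exposure-interaction column) of the design matrix, and average the
difference. Because the Q-model must keep the exposure as a predictor,
learners that cannot do so (e.g. random forests without per-arm fits) are
not offered.

## Design matrix

Continuous covariates enter through cubic b-splines; binary covariates pass
through unexpanded; every covariate-derived column is paired with an
exposure-interaction column (basis column × Z). Defaults and rationale:

* `spline_df = 3`, cubic, no interior knots — the minimal flexible cubic
  expansion; it keeps the parameter count manageable at n = 100 while
  allowing curvature. More df adds interior knots at equally spaced
  training quantiles. Configurable per analysis.
* Boundary knots sit at the training min/max. Rows evaluated outside the
  training range (bootstrap out-of-bag rows, new data) are **clamped** to
  the boundary before basis evaluation: cubic extrapolation beyond the
  support is wild and resampled cohorts hit it routinely.
* The constant basis column is dropped (the learner supplies the
  intercept); the retained columns plus the dropped one form a partition of
  unity, so all entries lie in [0, 1].
* Interactions are formed with the basis columns, not the raw covariate —
  "all interactions with the exposure" is read at the level of the design
  columns actually fitted.
* Scale-sensitive learners (NN, SVM) standardize inputs internally from
  the rows they are fitted on; penalized regressions standardize via their
  own conventions. The fitted design also records training z-score moments
  for callers that want a standardized matrix.

## Learners and tuning

Tuning maximises the mean held-out-fold AUC over an outcome-stratified
V-fold plan (default V = 10; fold sizes within each outcome class differ by
at most one). AUC is the rank-based (Mann–Whitney) statistic with ties
counting one half. The grid holds `grid_length = 20` candidate
combinations per learner: single-parameter learners span their range
(log-spaced for scales, consecutive integers for the network size);
multi-parameter learners use a seeded Latin hypercube, because a Cartesian
product over the four boosted-tree parameters would explode. A grid of
length one sits at the range midpoints (log-midpoint for scale
parameters). Exact CV ties go to the most parsimonious combination:
largest penalty, smallest network, smallest cost, fewest trees.

Default parameter ranges (all configurable): penalty strength λ ∈
[1e−4, 1e2] (fitted as C = 1/λ); elastic-net mixing ∈ [0, 1]; hidden-layer
size ∈ {1..20}; SVM cost ∈ [2⁻⁵, 2¹⁰] and kernel width = median-heuristic
γ × [2⁻³, 2³]; trees ∈ [50, 1000], depth ∈ [1, 4], learning rate ∈
[0.001, 0.3], minimum node size ∈ [5, 20]. These are wide, conventional
ranges; no claim of optimality is made.

Numerical choices: penalized solvers run at loose tolerance (liblinear
1e−2, saga 1e−3) — AUC-based selection is rank-based and insensitive to the
residual coefficient wobble (observed AUC shifts ~0.003, far below fold
noise), while tight tolerances dominate runtime at weak penalties. The
unpenalized reference logistic ("LR") uses IRLS, which reaches the exact
MLE; the saturated-model standardization identity is checked to 1e−10
against brute-force stratification. All fitted probabilities are clipped
to [1e−6, 1 − 1e−6] so no logit is infinite.

## Super learner

Members (default LLR, ELR, NN, SVM; boosted trees excluded) are tuned on a
shared fold plan; their out-of-fold predictions are combined as a weighted
linear predictor on the **logit scale** (probability-scale averaging is a
flag), with simplex-constrained weights maximising the out-of-fold AUC of
the combination. The AUC is piecewise constant in the weights, so the
search is gradient-free: candidate starts are the uniform point, every
vertex, and seeded Dirichlet draws, refined by pairwise mass transfers with
shrinking steps; strict-improvement acceptance means exact ties keep the
uniform combination, and vertex inclusion guarantees the ensemble's
out-of-fold AUC never falls below the best member's. A simplex grid search
serves as the test oracle for small libraries.

## Variance: bootstrap cross-validation

Refitting the entire tuning pipeline in every bootstrap iteration is
prohibitive, so tuning parameters are chosen once on the full sample and
frozen. Each of B = 500 (default) iterations draws n rows with
replacement, refits the Q-model on the resample, and evaluates the ACE on
the **out-of-bag** rows only (expected fraction (1 − 1/n)ⁿ ≈ 36.8%), so
overfitting of flexible learners does not leak optimism into the interval.
Super-learner weights *are* re-estimated inside each resample (weight
estimation is part of training), with a flag to freeze them; member tuning
parameters stay frozen either way. Degenerate resamples — a single outcome
or exposure class, or an empty out-of-bag set — are redrawn, at most 100
times per iteration, and counted in the report.

The SE is the sample SD of the draws; the default interval is the
percentile interval (the draw distribution is typically mildly skewed for
probabilities), with a normal-approximation interval behind a flag. The
reported point estimate is the full-sample fit, not the mean of the draws.

## Simulation scenarios

Covariates are drawn sequentially — each may depend linearly on covariates
already generated, so the graph is acyclic by construction — then Z and Y
are Bernoulli with logit-linear probabilities; covariate effects on the
outcome may be linear, quadratic (centred square) or step (threshold
indicator), plus optional exposure×covariate interactions.

Two presets bracket the difficulty range a Q-model faces in practice:
*realistic* (22 correlated covariates; 9 in the outcome model — 4 linear,
3 quadratic, 2 step — and one exposure×covariate interaction) and
*simplistic* (9 independent covariates; 6 linear effects; no interaction).
The preset **coefficient values are this package's own synthetic
calibration**, chosen once to give moderate prevalences (exposure
≈ 0.44/0.50, outcome ≈ 0.36/0.50) and a true risk difference near +0.14,
with genuine confounding (the crude contrast is ≈ 0.10 in the simplistic
scenario). Results on these presets characterise the estimator under the
stated mechanisms. What the generator does *not* emulate about
real cohorts: measurement error, missing data, informative sampling, and
non-logit-linear mechanisms — passing tests show estimator correctness
under the stated mechanisms, not robustness to those features.

The **theoretical ACE** is Monte Carlo: datasets are generated with Z ~
Bernoulli(z_prob) independent of X, a univariate logistic of Y on Z is
fitted per dataset, and expit(b0 + b1) − expit(b0) is averaged. For this
saturated one-predictor model the MLE contrast equals the difference of arm
means, which is how it is computed (an iterative GLM cross-check lives in
the tests); defaults are 1,000 datasets of n = 10,000 with z_prob = 0.5,
and the Monte-Carlo SE is reported so precision is checkable. Degenerate
datasets (an empty arm) are skipped and replaced.

## Performance criteria

Across replicates with estimates θ̂ᵣ, bootstrap SEs, and CIs, against a
true value θ: MB = 100 × mean(θ̂ᵣ − θ) (percentage points of the risk
difference); RMSE with the n denominator; ESD = sample SD (n − 1
denominator); ASD = mean SE; VEB = 100 × (ASD − ESD)/ESD on the SD scale
(variance-scale variant also reported); coverage = % of CIs containing θ;
power = % of CIs excluding 0 (the pipeline provides no other test
statistic). With these denominators RMSE² = (MB/100)² + ESD_uncorrected²
holds exactly. Calibration curves use equal-frequency bins; coincident
quantile edges merge bins.

## Determinism and problem sizes

Every random draw descends from a single seed: per-replicate seeds derive
from (master seed, replicate index) — independent of execution order — and
per-bootstrap-iteration streams from spawned seed sequences. Identical
configuration and seed reproduce results bit-for-bit.

The shipped tests and the acceptance script run scaled-down studies — e.g.
100–500 replicates with B in the 100–200 range, and tuning grids of length
8–10 with 5 folds in replicate loops — chosen as the package's own
desk-scale defaults; Monte-Carlo error at these sizes is a few points on
coverage/power and is stated alongside the checks. Publication-scale runs
(10,000 replicates, B = 500, grid 20, V = 10) use the same code paths via
configuration.

## Known limitations

* Binary exposure and outcome only; no survival outcomes, continuous or
  multi-level exposures, and no effect-on-the-treated estimand.
* No missing-data handling by design: validation rejects incomplete tables.
* The bootstrap-CV interval is approximate; with very rare exposure or
  outcome, redraw-censoring of degenerate resamples can bias the draw
  distribution.
* Doubly robust estimators (TMLE, double ML) and PS-based comparisons are
  out of scope.
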