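# Methods

This note documents the generative model behind the simulator, the
estimation details of the five classifiers, the numerical and design
choices that were genuinely open, and the limits of what the simulation
can show about real data.

## Generative model

A design cell fixes six factors: the number of known groups *G* (2 or
3), the total sample size *N*, the known-group proportions, the subgroup
proportions applied within every group, the standardized group
separation δ, and the standardized subgroup separation *s*.

Predictors are p = 5 jointly normal variables with unit SDs and a fixed
correlation matrix; the default is the published correlation matrix of
the first five WAIS-III subscales, chosen as a realistic
social-science correlation structure (entries 0.36–0.76). Because all
SDs are 1, the shared covariance equals the correlation matrix, and it
is identical across all groups and subgroups.

Mean structure (per predictor, identical in every coordinate):

* group *g* (1-indexed) has base mean (g−1)·δ, so adjacent groups are
  separated by δ on every predictor;
* within a group, the *base* subgroup sits at the base mean and the
  second subgroup at base + s·direction, where direction points toward
  the neighbouring group for end groups (+1 for group 1, −1 for group
  *G*) and +1 for the middle group of three. The middle-group direction
  is a pure convention: nothing in the symmetric layout distinguishes
  the two choices, and the end-group results are insensitive to it.
* s = 0 collapses both subgroups onto one mean — the homogeneous
  control. At δ = s = 0.2 (two groups) the two groups' subgroup-mean
  sets coincide: complete distributional overlap, the most extreme case
  the design can express.

Cell counts are deterministic, not multinomial: group totals and then
within-group subgroup counts are apportioned by largest remainder, with
fractional-seat ties resolved toward the larger cell. The larger
subgroup share always goes to the base subgroup (the one farthest from
the neighbouring group). This keeps size ratios exact in every
replicate, so between-replicate variance reflects sampling of predictor
values only.

Draws use a Cholesky factor of the covariance applied to standard-normal
variates from a `numpy` PCG64 generator; a non-PSD covariance is
rejected with the offending eigenvalue named. Each replicate produces a
training sample and an independent cross-validation sample of the same
size from the same population. Seeding is hierarchical
(`SeedSequence((master_seed, cell_index, replicate_index))`), making
every cell and replicate independent and the whole grid reproducible
bit for bit from one master seed.

## Classifiers

All five methods implement `fit(train) → model` and
`predict(model, X) → (labels, posteriors)`; posterior rows are
nonnegative and sum to 1, labels are the posterior argmax with ties
broken to the lowest class index (uniformly, in every method). Only the
known-group labels are ever shown to a method.

**LDA.** Class means, pooled within-class covariance, priors from the
training class frequencies (optionally uniform). The pooled covariance
uses the maximum-likelihood denominator *n* rather than *n − K*, so the
one-subclass mixture model below reduces to LDA *exactly*; at the
benchmark's sample sizes the difference is negligible for
classification. A singular covariance is ridged by 1e−8 × mean diagonal
with a warning.

**Multinomial logistic regression.** Baseline-category logit (reference
= highest class) fitted by full Newton steps on the multinomial
log-likelihood with backtracking; convergence when the log-likelihood
improvement falls below `tol · (|ll| + 1)` (default 1e−8, ≤ 50
iterations). Under complete or quasi-separation the likelihood has no
maximizer; fitting stops (cap or saturation of the linear predictor
beyond ±30) with a warning, and the saturated posteriors remain usable.
The fit agrees with an independent IRLS implementation (statsmodels) to
1e−5 in the tests.

**CART.** Greedy binary tree, node deviance
D = −2·Σₖ nₖ·log(nₖ/n). A split is accepted only if both children hold
≥ 10 rows and the deviance reduction is ≥ 0.01 × *root* deviance.
Reading the "minimum deviance to split" as a reduction threshold
*relative to the root* makes the rule scale-invariant (deviance grows
linearly in n; an absolute threshold would effectively vanish at large
N); it also implies any node with ≤ 19 rows is terminal. Candidate
thresholds are midpoints of adjacent distinct values; the first strictly
better candidate wins (features in index order, thresholds ascending),
so ties are deterministic. Leaves report class proportions as
posteriors. Tree growth is verified against an exhaustive plain-Python
split search on small fixtures.

**GAM.** Additive logistic model: each non-constant predictor is
standardized and expanded into a cubic spline basis with a fixed target
of 4 degrees of freedom (cubic polynomial plus truncated cubic terms at
interior quantile knots — the regression-spline form of a fixed-df
cubic smooth; smoothness is controlled by basis dimension, not a
penalty). The binomial logit on the pooled basis is fitted by IRLS,
stopping when the relative deviance change is below ε = 7e−7 or at 30
iterations. Constant predictor columns receive no basis columns and
contribute nothing beyond the intercept.

With three classes the binary-logit smoother needs a multiclass
mechanism, and two are provided. `"ovr"` fits one-vs-rest models and
renormalizes the class scores. The default `"ordinal"` maps the class
index onto an equally spaced grid in [0, 1], fits a single binomial
model to that fractional response, and classifies to the nearest grid
point (posteriors are triangular interpolation weights on the grid, so
the argmax is the nearest point and rows sum to 1). The ordinal
mechanism deliberately mirrors how a binary-logit additive model tends
to be pressed into service for ordered groups, and it reproduces the
characteristic failure mode the benchmark observes for this method:
fitted probabilities concentrate near the middle of the scale, so the
middle group is over-predicted — low middle-group error, high end-group
error, the reverse of every other method. One-vs-rest behaves like the
linear methods and shows no such reversal.

**MIXDA.** Each class *k* is a mixture Σᵣ π_kr·φ(x; μ_kr, Σ) of R
Gaussian subclasses (default R = 2, matching the simulated truth;
configurable) with one covariance shared across *all* subclasses of all
classes, estimated by EM over within-class subclass responsibilities.
Class labels are observed, so the E-step normalizes responsibilities
within each observation's own class; the M-step updates means, mixing
proportions and the shared ML covariance. The observed-data
log-likelihood (including the class-prior terms) is non-decreasing by
construction and is exposed as `loglik_path_`; convergence is declared
at relative change < 5e−5 (≤ 100 iterations). Initialization is
deterministic — farthest-point seeding within each class (first the
point farthest from the class centroid, then points maximizing distance
to chosen centers) followed by hard assignment — so refits are
bit-identical. A subclass whose responsibility mass vanishes is
re-seeded from the farthest in-class point with a warning; singular
covariances are ridged as in LDA. Class posteriors combine the mixture
densities with data-estimated class priors, and
`subclass_responsibilities` returns the latent-subgroup readout.

## Metrics and aggregation

Overall misclassification is the number of wrongly labeled rows over
the total; by-group rates divide each group's errors by that group's
size, and the size-weighted mean of group rates equals the overall rate
to 1e−12 (asserted on every replicate). Aggregation over replicates and
collapsed factors is the unweighted mean of per-replicate rates; all
cells of the full cross share one replicate count, so this matches
per-observation pooling up to negligible rounding. Summary tables also
report per-method marginal min/max/median/mean/IQR over the grouped
cells, and the equal→75/25 subgroup-ratio increase series (unequal-cell
mean minus equal-cell mean, negative values legitimate).

## Problem sizes

The default grid replicates each cell 1000 times. The bundled
acceptance script and the heavier tests use the package's scaled-down
defaults — the full 180-cell three-group cross at 50 replicates per
cell for the four fast methods, and a reduced one-factor grid (N = 150,
equal ratios, δ = 0.5, all five overlaps) at 200 replicates for
rank-order checks including GAM — sizes chosen so a complete rerun
takes minutes on one CPU while keeping Monte Carlo error in a cell mean
near 0.01. The `--reps` flag and `ExperimentGrid.replicates` restore
the full design.

## A note on attainable error

Because the predictors are exactly Gaussian with a covariance shared by
every group and subgroup, the population-optimal (Bayes) rule is
available in closed form, and `population_bayes_rate` estimates its
error by Monte Carlo for any design cell. Two consequences matter when
reading results. First, at the benchmark's separations the groups
overlap heavily, so *all* methods sit at high absolute error (for three
equal groups at δ = 0.5 the floor is near 0.5); differences between
methods are therefore small. Second, the Bayes rule here is
log-quadratic and nearly linear in x, so correctly specified linear
methods (LDA, logistic regression) operate near the floor by
construction, and no tree or spline method can undercut them on this
data-generating process — flexible methods can only pay a variance
penalty. The tests assert that no fitted method beats the computed
floor beyond sampling slack.

## Limitations

* The simulator emulates mean-shifted Gaussian mixtures with a common
  covariance and exactly two subgroups per group; real diagnostic data
  involve non-normal predictors, covariances that differ across groups,
  more (or unknown numbers of) latent classes, and measurement error.
  Passing tests show correctness of the implementation under the stated
  model, not robustness of any method beyond it.
* Group mean differences are applied uniformly to every predictor;
  separations concentrated in a few predictors would favor
  variable-selecting methods (trees) more than this layout does.
* The GAM multiclass mechanism for ≥ 3 groups is a modeling choice (see
  above); its results should be read as "what a binary-logit additive
  model does when forced onto ordered groups", not as the best additive
  classifier.
* CART is grown without pruning or cost-complexity tuning, and GAM's
  smoothing is fixed-df rather than selected by cross-validation — both
  by design, to keep the methods at their stated settings.
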