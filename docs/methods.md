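# Methods

## Model and procedure

The package detects, per continuous variable, up to two outcome-rate
thresholds — one below and one above the median — and builds
classifiers from the resulting binary flags.

**Baseline.** The comparison group for a variable is its interquartile
range: observations with p25 ≤ x ≤ p75 (inclusive), where the quartiles
and the median use linear-interpolation (type-7) quantiles. The
convention is configurable (`UfaConfig.percentile_method`) because
quantile definitions differ across software and the choice moves cuts
by at most one data point at realistic sample sizes.

**Candidate grid.** On each side of the median the `min_support_excluded`
(default 5) most extreme non-missing values are trimmed by order
statistic, then the interval from the trimmed extremum to the median is
divided into `n_segments` (default 50) equal-length segments whose
interior breakpoints are the candidates. Trimming by order statistic —
rather than dropping candidates post hoc — keeps the grid construction
well defined under heavy ties at the extremum and guarantees every
candidate tail contains at least `min_support_excluded + 1`
observations. Tails are strict (`x < cut` below, `x > cut` above): grid
points are generically not data values, and a value exactly at a cut is
evidence of neither extreme, so it stays with the central mass. The
candidate region may overlap the IQR baseline (candidates between p25
and the median); the two groups are used as defined, without
disjointing, because the statistic is a screening device rather than a
formal two-sample design.

**Statistic.** Candidates are scored by the pooled two-proportion Z
(README formula). Degenerate pooled rates (0 or 1 — both groups
unanimous and identical) are defined as Z = 0: unanimity in both groups
is no evidence of separation. The candidate maximising |Z| wins; exact
ties go to the candidate closest to the median, i.e. the one with the
greatest support. Significance is |Z| ≥ `critical_value` (default
2.576, two-sided p = 0.01), boundary inclusive.

**Multiplicity.** The scan performs ~50 tests per variable side, so the
per-variable-side false-detection rate under independence is several
percent, not 1% — the acceptance suite measures it against an
independent Monte-Carlo oracle rather than against the nominal level.
No correction is applied by default; the intended workflow validates
thresholds on held-out data. `UfaConfig(bonferroni=True)` optionally
tightens the critical value to hold the family-wise level across every
Z evaluation of the detection run.

**Missing data.** An observation missing a variable is excluded from
that variable's baseline, grid and tails, but participates fully in
every other variable's search (detection for variable *w* depends only
on (x_w, y) pairs with x_w observed). At flag time a missing value
raises no flag: an unobserved measurement cannot evidence an extreme.

**Targets.** The public contract is a binary 0/1 outcome. A continuous
outcome in [0, 1] is accepted behind `Dataset(..., continuous_target=True)`,
in which case all group "rates" become group means; the Z statistic is
then a heuristic screen, not a calibrated binomial test, and the option
exists for exploratory use only.

## Classifiers

**N-UFA.** Observations are reduced to (n_high, n_low) flag counts,
each flag weighted one. The default boundary is a closed-form
two-class Fisher discriminant with priors from training frequencies —
deterministic, and exposed as an explicit `LinearBoundary` so users can
inspect or override it. When the pooled within-class scatter is
singular (common when only one flag direction exists), the fit falls
back to a midpoint threshold on n_high − n_low, logged. An exhaustive
mode (`method="exhaustive"`) minimises training misclassifications
exactly by sweeping every direction defined by a pair of distinct count
points plus the axis directions, and every split of the projected
values, breaking ties toward the larger margin; it is exact because
counts live on a small integer grid, and is provided because a
minimum-error linear boundary is the natural alternative reading of
the flag-plane picture. Score 0 classifies as the positive class.
Training with no significant thresholds degrades to the training
majority class with a flat score, keeping harness runs on
uninformative data well defined.

**RF-UFA and comparators.** The flag matrix is handed to a scikit-learn
random forest with default hyperparameters; logistic regression
(lbfgs, L2, max_iter=1000), random forest, SVC, k-NN and decision tree
baselines run on mean-imputed continuous inputs, imputation means
learned on training splits only. These are reference points wrapped in
thin adapters, not contributions.

## Synthetic data

The generator emulates a clinical risk table: i.i.d. continuous
variables (uniform on [0, 1] by default, standard normal optionally),
a binary outcome with configurable base rate, and planted thresholds —
beyond a known cut on a known side, the outcome probability switches to
a known tail rate. A variable may carry one planted tail per side
(e.g. both hypo- and hyper-extremes risky). When tails overlap in row
space the outcome probability is the maximum of the occupied tails'
rates, else the base rate; maximum-composition reflects "the most
severe derangement dominates" and keeps every planted threshold's
marginal tail rate interpretable. Quantile-specified cuts resolve
against the theoretical marginal quantile, so ground truth is exact.

Deliberately not emulated: correlation between variables, measurement
error structure, informative missingness, and the p ≈ n regime of wide
clinical tables. Consequences for interpreting results are noted under
Limitations.

Perturbation operators mirror standard robustness protocols:
`inject_missing` blanks each variable cell independently with the given
probability (MCAR per cell — the simplest reading of "replaced
randomly"; per-row schemes are out of scope), never touching the
outcome; `inject_noise` adds, to a random fraction of non-missing
cells, Gaussian noise with zero mean and the column's empirical
variance (computed on unperturbed data, ddof = 1), leaving constant
columns untouched with a warning. A column perturbed at fraction f has
variance ≈ var·(1 + f), which the tests verify.

## Evaluation harness

Stratified k-fold cross-validation (default k = 10) and repeated
stratified holdout (default 100 runs; larger counts available by
argument) report accuracy in percent and AUROC, as mean ± 1.96
standard errors over folds/runs — the interval construction is stated
explicitly because reporting conventions vary. Everything constituting
model fitting — threshold detection, boundary fitting, imputation
means, estimator training — happens inside training splits only; the
leakage tests verify that shuffling held-out labels changes neither
detected thresholds nor fitted boundaries. Robustness sweeps perturb
the whole table once per fraction (as in the protocols they mirror)
and re-run the split/detect/fit/score cycle on the perturbed table,
reporting deltas from the 0% row. A fold whose test split contains one
class leaves AUROC undefined (NaN, excluded from the mean); a constant
score on a two-class fold scores AUROC 0.5.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, chosen
as the smallest sizes at which the measured properties are stable:
planted-cut recovery uses n = 2000 with 100 replicates; null
calibration uses 1000 variables of n = 500 per implementation;
robustness comparisons use n = 1000 tables with 10 planted (five
10%-prevalence high-risk tails at rate 0.75, five low-risk at 0.05
against base rate 0.2 — roughly 3x relative-risk extremes, strong
enough that classifiers operate clear of the majority-rate floor) plus
10 noise variables over 20 seeds. Floats round-trip through report
CSVs via `%.17g` and round-trip parsing. All stochastic operations
take explicit seeds; detection itself is deterministic, and per-variable
results are independent, so evaluation order cannot change output.

## Limitations

* With independent variables and maximum-composition outcomes,
  overlapping planted tails dilute each variable's marginal effect;
  aggregate signal saturates well below what correlated real tables
  exhibit. Passing recovery tests therefore demonstrate correctness of
  the search, not performance on correlated data.
* Robustness comparisons against imputed baselines at these sizes show
  the flag classifiers retaining a higher absolute accuracy under heavy
  missingness; the much larger *relative* degradation of imputed
  models reported on wide clinical tables arises from feature counts
  comparable to sample size and correlated redundancy, which the
  generator intentionally does not reproduce.
* The candidate grid is fixed and equal-length; no uncertainty is
  attached to a detected cut (no bootstrap), and no false-discovery
  procedure beyond the optional Bonferroni toggle is provided.
* Flags are equally weighted; unequal weighting and nonlinear
  flag-plane boundaries are out of scope.
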