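# Methods

## The weighted-ERM model

We assume m labelled samples drawn i.i.d. from a source distribution P_s
and n ≪ m from a target distribution P_t ≠ P_s, and we want a predictor
that minimizes the *target* population risk R_t(θ) = −E_{P_t}[log p_θ(y|x)].
The weighted empirical risk

R̂_α(θ) = (1−α) R̂_s(θ) + α R̂_t(θ) + Ω(θ)

interpolates between source-only fitting (α = 0), unweighted pooling
(α = n/(m+n)) and target-only fitting (α = 1). The implementation realises
the objective as per-sample weights — (1−α)/m on source rows, α/n on
target rows — so any learner that accepts `sample_weight` (logistic/linear
models, boosted trees, random forests, the stacking ensemble) minimizes it
without modification. Internally the weights are rescaled by a uniform
factor m+n before being passed to the learner, so that the uniform-weight
case coincides exactly with an unweighted fit and regularization strengths
keep their conventional meaning; a uniform rescaling does not change the
minimizer of the data term.

Two exact identities are load-bearing and tested: α = n/(m+n) reproduces
pooled ERM, and for convex learners the weighted fit equals a fit on a
dataset where rows are replicated proportionally to their weights.

### Choosing α

The candidate grid is α = k/(k+1) for k = 1…10 ({0.5, …, 10/11}); its
spacing 1/((k+1)(k+2)) shrinks toward α = 1, where the optimum sits when
the shift is large. α is selected per outer fold by an inner five-fold
cross-validation in which source and target rows are folded separately
(stratified by label) and paired, so every inner fold carries an equal
share of the scarce target data. The selection criterion mirrors the outer
reporting metric (AUC for classification, negative MAE for regression),
evaluated on the held-out *target* rows; because each inner fold may hold
only a handful of target rows, held-out predictions are pooled across the
five inner folds into a single score per candidate rather than averaged
fold-wise (a per-fold AUC over two or three rows is frequently undefined).
Ties return the smallest candidate, preferring the larger source sample.
α = 0 is always evaluated as an explicit source-only baseline row of the
CV table but is never selectable when target data is in use. Selecting α
per outer fold (rather than once globally) is the strictly leak-free
reading of the nested protocol; a global selection would reuse outer-fold
information.

### The bound

The excess target risk of the weighted-ERM minimizer is bounded by
4·√((α²/n + (1−α)²/m)(V − log δ)) + 2(1−α)·d(P_s, P_t), with V a
VC-dimension proxy and d a source–target discrepancy. The expression is
convex in α (a norm of an affine map plus a linear term), so the
implementation resolves boundary optima exactly from endpoint derivative
signs — in particular α* = 1 if and only if n ≥ 4(V − log δ)/d², the
threshold beyond which source data cannot reduce the bound — and finds
interior optima by bounded scalar minimization (xatol 1e-10) seeded from a
dense grid. At d = 0 the closed form α* = n/(m+n) is returned directly.
V and d are hard to estimate in practice; the module ships deliberately
simple heuristics (parameter count for V; √max(MMD², 0) for d) that are
kept separate from the exact arithmetic, and cross-validated α remains the
recommended choice.

## Shift quantification

Distribution shift between groups is measured with the unbiased MMD²
U-statistic

MMD²_u = 1/(n²−n) Σ_{i≠j} [k(x_i,x_j) + k(x′_i,x′_j) − k(x_i,x′_j) − k(x_j,x′_i)],

whose unbiasedness implies it can be negative; identical inputs give
exactly zero. The kernel is the inner product of a *learned* feature map:
a single MLP with a shared ReLU trunk (three hidden layers, default widths
64-64-32) and one softmax head per stratification attribute (sex, age
band, race, study), trained with Adam on the summed per-head
cross-entropies. Using one joint network rather than one per attribute
keeps the embedding shared, so MMD values are comparable *across*
attributes; the trunk output is used raw, without re-normalization.
Significance comes from a permutation test that pools the 2n embeddings
and reassigns group membership B times preserving sizes, with
p = (1 + #{perm ≥ obs})/(1 + B), so p is never below 1/(B+1); B defaults
to 9999 where p < 10⁻⁴ resolution is wanted, and smaller B is fine for
screening. Unequal group sizes are handled by seeded subsampling of the
larger group, since the equal-n form of the estimator is used throughout.
Pairwise group matrices feed average-linkage hierarchical clustering on
distances max(MMD², 0).

Caveat: when the feature map is trained on the same rows it embeds, the
network memorizes chance differences and inflates the statistic even
between identically distributed groups. Orderings of pairs are the
interpretable output; calibrated p-values require embedding held-out rows.
The absolute scale of the statistic also depends on trunk width and
training length, so values are not comparable across differently
configured runs.

## Preprocessing

Continuous features: missing values are imputed with the training median,
then the column is z-scored to mean 0, variance 1 under the *population*
convention (divide by n). Columns whose sample skewness |g₁| exceeds 1
(biased moment estimator; threshold configurable) are instead
quantile-normalized: training values map to Φ⁻¹((r − 0.5)/n) with average
ranks for ties, and new values are placed by linear interpolation on the
stored map. Discrete features are one-hot encoded over the training
vocabulary plus a reserved unknown category that absorbs both missing
entries and categories unseen at fit time. For each feature with any
missing value at fit time — and only those — a binary indicator column is
appended, preserving the information in the absence itself. The state is
a pure function of the training rows (the leakage contract the nested
protocol relies on, enforced by a mutation test) and serializes to JSON
for exact reuse across folds. No batch or site harmonization is applied.

## Evaluation protocol

The target group is split into five label-stratified folds. Setting
"all": four folds train, one tests. Setting "10%": all source data plus
⌊0.1 n⌋ rows of the held-in fold train, the four complementary folds
(≈80%) test, and the remainder of the held-in fold stays deliberately
unused — uniform bookkeeping across many source/target pairs, at the cost
of a tenth of the target data. Setting "0%": one fold-less evaluation on
the entire target group. Reported dispersion is the standard deviation of
the five fold metrics, not a pooled recomputation; configurations are
compared by a two-sided paired t-test over fold metrics. Fairness is
audited on the pooled test predictions: DPD is the max−min gap in
positive-prediction rate across groups of a sensitive attribute, EOD the
larger of the TPR and FPR max−min gaps; scores are thresholded at 0.5
(configurable), and a group empty at some label stratum is skipped for
that stratum.

## Stacking ensemble

Five base families — k-NN, random forest, gradient-boosted trees, MLP,
logistic/linear — produce out-of-fold predictions via repeated stratified
k-fold bagging (defaults k = 5, 2 repeats, averaged), so no model ever
predicts a row it saw. The OOF columns concatenated with the original
features (a skip connection) train one stacking level — exactly two levels
total, the standard guard against stack overfitting — and the stacked
models are blended by greedy forward selection with replacement (default
25 iterations) minimizing validation log loss / squared error on a
held-out fifth of the training rows. The first greedy pick is the best
single model, so the blend never validates worse than it. Sample weights
thread through every layer; k-NN and the sklearn MLP lack native weight
support and fall back to a seeded weighted bootstrap resample. Base
hyper-parameters are small fixed settings; absolute accuracies will
differ from what a large tuned framework achieves, and tie-breaks in
greedy selection go to the lowest candidate index, deterministically.

## Downstream clinical procedures

MCI progression: the AD classifier's probability output on baseline MCI
subjects is the single covariate of a two-class LDA (pooled within-class
variance, empirical priors) for pMCI-vs-sMCI and pMCI-vs-nMCI separately.
Each of five stratified folds serves once as the ~20% training fraction,
the rest testing — the inverse of the usual CV geometry, reflecting how
few progression labels are typically available. Under equal priors and
variances the 1-D boundary sits exactly at the class-mean midpoint. A
constant covariate degenerates LDA; the implementation falls back to
prior-probability scores, giving chance AUC.

Brain-age residuals: BAR = predicted − chronological age, in years;
positive values suggest accelerated aging. Pearson r against each
clinical variable is computed over the observed pairs only, with two-sided
p-values from the exact t-transform of r and a significance flag at
p < 0.01; constant variables and variables with fewer than 3 observed
pairs are reported as missing with a reason. No age-bias correction of
BAR is applied.

## Synthetic cohorts: what they emulate and what they do not

The generator draws numeric features from per-group Gaussians with
configurable mean offsets and covariance scale factors; designated columns
are exponentiated to log-normal marginals to exercise quantile
normalization. Labels come from per-group logistic (diagnosis) or linear
(age) models — differing per-group coefficients produce the concept shift
that makes adaptation matter. Class balance is realised by calibrating
each group's intercept on the sampled linear predictor (bisection to the
requested positive rate). Missingness is injected MCAR at per-column
rates, a deliberate simplification: real clinical missingness is
structured (by study, instrument, and visit), and no per-feature rates
are published for the consortium data, so rates are configurable rather
than calibrated. Progression labels are generated cross-sectionally from
a latent severity score: per-class logits tilt with the AD-direction
score (ordered pMCI > sMCI > nMCI) and intercepts are calibrated by
iterative proportional fitting so marginal class frequencies match the
requested priors — real labels are longitudinal, but the artifact only
needs AD-correlated label structure. Everything is reproducible from
(spec, seed).

The benchmark condition (`adaptation_benchmark_spec`) fixes the study
conditions used throughout the tests and the acceptance script: 1000
source and 200 target subjects, 15 numeric features, a 0.5σ covariate
shift on the five signal-carrying features, and a target label model with
part of the signal rotated onto a new feature and one coefficient flipped.
Passing tests on these cohorts demonstrate the mechanism — transfer
degrades under shift and few-shot weighting recovers it — not clinical
performance levels: the synthetic tables have no site effects, no
longitudinal structure, no feature correlations beyond the label models,
and far fewer features than a real imaging-derived table.

## Numerical choices and problem sizes

Probabilities are clipped at 1e-12 before logs so degenerate learners
yield finite objectives. MMD permutation loops precompute the pooled Gram
matrix once per test. The calibration studies in the test suite and
acceptance script use 500 null and 200 shifted replicates at n = 100 per
side with B = 199 permutations, and the adaptation benchmark uses 50
replicates of the m = 1000 / n = 200 condition with a logistic learner —
sizes chosen to make the binomial acceptance intervals informative while a
full run stays in the low minutes on one core. Stochastic checks fix seeds
and assert within pre-stated binomial/multinomial 99% intervals.

## Known limitations

- The MMD feature map is trained and evaluated on the same rows by
  default (orderings, not calibrated p-values; see above).
- The equal-n estimator subsamples unequal groups rather than using an
  unequal-n U-statistic.
- No multiple-testing correction across group pairs in the shift report;
  values are reported raw.
- The ensemble's hyper-parameter spaces are intentionally small and fixed.
- The bound's V and d heuristics are crude; the bound guides intuition
  and sanity-checks CV, it is not numerically tight.
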