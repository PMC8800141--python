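# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Data-generating processes

Two individual-level models produce a binary outcome over 192 social
intersections (4·2·2·2·2·3 category combinations of six inputs).

**Covariates.** X2 ~ Bernoulli(0.2), X3 ~ Bernoulli(0.5),
X5 ~ Bernoulli(0.25); X4 is mediated by X3 with P(X4=1|X3=0)=0.4 and
P(X4=1|X3=1)=0.7.  In the categorical model X1 is uniform over 4 categories
and X6 uniform over 3; in the mixed model X1, X6 ~ N(0,1) and are binned
into *sample* quartiles/tertiles to form intersections (cut points are
recomputed per generated dataset, because intersections are formed from the
observed data for prediction, not from theoretical quantiles).

**Risk model.** The outcome probability is exp(linear predictor):
log-linear (not logistic), so sampled coefficients are log relative risks.
The categorical model carries X1-category effects, X2–X5 effects, the
(X1=2)&X2 and (X1=3)&X2 interactions, and the X3·X4·X5 triple interaction;
the mixed model carries a linear X1 slope, X2–X5, an X1·X2 interaction
gated to X1>1 & X2=1, and the same triple interaction.  X6 never enters the
risk: it is the null variable that a good variable-selection procedure
should rank last.

**Effect sizes.** Each iteration draws fresh effects on the relative-risk
scale from N(1, 0.30) truncated to a two-window union that excludes
near-null values — rare tier [0.20, 0.76] ∪ [1.24, 1.80], common tier
[0.20, 0.89] ∪ [1.11, 1.80] — so every variable is either clearly
protective or clearly harmful, with the sign decided by which window the
rejection sampling lands in.  Interaction terms use the same distribution;
the `interaction_boost` sensitivity variant restricts interactions to the
harmful (upper) window only.  Intercepts: −3 (rare, baseline risk 4.98%),
−1.5 (common, 22.3%), log 0.5 (the 50% sensitivity tier, chosen so the
all-null draw yields exactly 50%).

**Admissibility.** A whole coefficient draw is rejected and redrawn (bound:
1000 redraws, then an explicit error) whenever it could give an individual
a probability above 1.  For the categorical model this is checked
analytically over all 64 risk-relevant covariate patterns, which also
guarantees every intersection's true prevalence is a valid probability.
For the mixed model no universal guarantee exists (X1 is unbounded), so the
check is against the realised sample; the covariate sample is drawn once
per iteration and only the coefficients are redrawn.

**Truth.** The true prevalence P_i of intersection i is the generating
formula evaluated at the intersection's covariate pattern (categorical
model; defined for all 192 cells) or the mean of members' true
probabilities (mixed model; undefined for empty cells).  The binary
sampling step never touches the truth.

**Realised calibration.** Under this sampler the mean realised prevalence
at N=50,000 (categorical inputs) is ≈4.9% for the rare tier and ≈22% for
the common tier — close to the all-null baselines, as expected for a
sampler that is symmetric about RR = 1 (the realised prevalence is
multilinear in the sampled RRs, so its expectation sits at the baseline).
Pushing the mean materially below baseline would require an asymmetric
(predominantly protective) effect distribution, which nothing in the
two-window construction provides.  This is a known property of the design,
not a target of the implementation; the acceptance report states the values
actually computed.  The 50% tier behaves accordingly: its admissibility
bound (positive pattern sums ≤ log 2) rejects most harmful draws, so its
realised prevalence averages below 50%; run metadata records the realised
values.

**Seeding.** A scenario's master seed spawns one child `SeedSequence` per
iteration (`spawn_key=(iteration,)`), so any iteration is reproducible in
isolation and results are invariant to execution order and parallelism.

## Estimators

**Cross-classification** is the raw within-intersection event proportion;
empty intersections have no estimate.

**Modified Poisson regression** (main-effects, correctly specified,
saturated) fits the Poisson likelihood with log link to the binary outcome
and reports the sandwich covariance A⁻¹BA⁻¹ (bread = expected information,
meat = summed score outer products).  Designs use treatment coding built in
a fixed column order; aliased columns are removed by a Gram–Schmidt sweep
in that order, deterministically.  The correctly specified design adds
X1:X2, X3:X4, X4:X5, X3:X5 and X3:X4:X5 to the main effects; the saturated
design is the full factorial product expansion (192 columns categorical,
64 mixed, continuous variables entering linearly — the natural reading of
"all interactions" when some inputs are continuous).  For all-categorical
data the IRLS runs on rows aggregated by unique (pattern, outcome) with
frequency weights, which is exact and makes saturated fits cheap at any N.
Convergence follows the reference GLM semantics: relative deviance change
< 1e−8 within 25 iterations, finite coefficients, step-halving only when a
step yields a non-finite deviance, and failure when halving is exhausted or
the first step is invalid.  Log-link predictions can exceed 1; they are
clipped to [0, 1] with a logged clip count.  Intersection predictions are
taken at the 192 covariate patterns (categorical) or as member-averaged
individual predictions (mixed) — member averaging was chosen over
bin-midpoint prediction because it is well defined for any binning and
consistent with how the truth is defined for the mixed model.

A note on saturated-model convergence: fits that drive zero-event cells
toward zero converge cleanly here at every sample size.  Reference GLM
implementations can instead abort on such designs (first-iteration overflow
with no fallback iterate, and near-aliased columns surviving per-iteration
rank detection); this implementation removes exact aliasing up front and
therefore converges where those numerics fail.  Convergence proportions
reported by this package measure the statistics, not solver fragility.

**MAIHDA** is a binomial GLMM with logit link, fixed main effects for
X1–X6 and one random intercept per intersection, fitted by
Laplace-approximated ML: for each candidate variance σ² the joint penalised
likelihood over (β, u) is maximised by Newton steps (Schur complement on
the diagonal random-effect block; step-halving keeps the concave objective
non-decreasing), and the profiled Laplace likelihood
ℓ(σ²) = log p(y|β̂,û) − ‖û‖²/2σ² − ½Σ log(1+σ²Wᵢ) is maximised over log σ²
by bounded scalar optimisation.  σ² = 0 is a valid boundary solution
(plain logistic regression) and is reported as such.  Adaptive quadrature
is unnecessary for a single scalar random effect; agreement with the
reference Laplace implementation is at the 4th decimal on shared fixtures
(frozen in the test suite).  Predictions are inverse-logit of fixed part
plus BLUP, with BLUP 0 for unseen intersections, member-averaged for the
mixed model.

**CART** wraps the scikit-learn Gini tree (minimum node size to split 20)
with cost-complexity pruning: candidate penalties are the geometric
midpoints of the pruning path and the final penalty minimises 10-fold
cross-validated *misclassification* error, ties broken toward the strongest
pruning.  Misclassification (rather than deviance) is the error the
reference classification-tree implementation cross-validates by default,
and it is what produces the characteristic behaviour for low-prevalence
outcomes: no subtree changes the all-negative classification, all CV errors
tie, and the tree collapses to the root, estimating every intersection at
the sample prevalence.

**CTree** tests each candidate variable at a node with the asymptotic
chi-square form of the permutation statistic (contingency chi-square for
categorical, squared-correlation trend statistic for continuous),
Bonferroni-multiplies the smallest p-value by the number of candidates, and
stops when it exceeds α = 0.05 or the node is below 20 individuals.  The
winning variable is split at the binary partition (category subset or
cutpoint) maximising the two-sample chi-square statistic; children must
hold ≥ 7 individuals.  Ties go to the smallest variable index,
deterministically.  The full influence-function framework of the reference
is not reproduced; at these sample sizes the asymptotic approximation
matches its default behaviour.

**CHAID** (all-categorical inputs only; it raises otherwise) merges, per
variable, the least-significantly-different pair of category groups while
that pair's 2×2 chi-square p-value exceeds 0.05, then Bonferroni-adjusts
the merged table's p-value by the Kass multiplier (the number of ways to
partition the original categories into the merged group count) and splits
multiway on the variable with the smallest adjusted p ≤ 0.05.  Re-splitting
of merged groups of three or more is omitted.  The adjustment is
deliberately *within-variable* only — canonical CHAID does not correct
across candidate variables, which is why its splitting rates sit slightly
above CTree's; the type-I-error test therefore checks CHAID per variable
and CTree familywise.

**Random forest**: 500 bagged Gini trees, terminal node size 1, mtry tuned
over the full grid 1..6 (step 1) by out-of-bag Brier score (smallest mtry
on ties).  Impurity VIM is the per-variable total Gini decrease averaged
over trees (reported on the training-count scale; only relative magnitudes
are meaningful).  Permutation VIM uses held-in permutation importance with
a Brier scoring rule; its p-values are Altmann-style: the response is
permuted and the forest refitted B times (default 100) at the selected
mtry, and p = (1 + #{null ≥ observed})/(B + 1).  Categorical features are
ordinal-coded for CART and the forest (binary splits on codes), a standard
concession of array-based tree stacks; CTree and CHAID treat categories as
unordered sets.

## Evaluation

`compute_mad` averages |P̂ᵢ − Pᵢ|/p over intersections with equal weight
per intersection.  Intersections empty in the realised sample are excluded
with the divisor reduced accordingly (an undefined estimate cannot be
averaged; the exclusion count is logged).  A missing estimate for a
*populated* intersection is an error, not a silent exclusion.
Non-converged fits contribute convergence rows but no MAD.  Bias and
variance across iterations at a fixed coefficient draw are reported in
percentage points and squared percentage points (×100 and ×100²), the scale
on which binomial sampling variance 10⁴·P(1−P)/n is readable; the functions
refuse mixed coefficient draws.

## Problem sizes

The full study design (1000 iterations × 4 sample sizes × 4 scenarios) is
available through `RunConfig`, but the shipped tests and the acceptance
script use scaled-down grids chosen as desk-scale replications: 50–200
iterations, N between 2000 and 50,000.  Monte-Carlo tolerances in the tests
are set from binomial/normal error at those sizes.

## The blood-pressure fixture

`generate_nhanes_like_fixture` is a synthetic stand-in for a survey
extract: 2 sex/gender × 5 race/ethnicity × 3 age-group × 2 poverty
categories (60 intersections), three systolic and diastolic readings per
person from a latent-mean model in which age dominates, with occasional
missing third readings.  Constants were tuned once, by Monte-Carlo, so the
averaged-readings rule (systolic ≥ 130 or diastolic ≥ 80 mmHg) yields ≈41%
marginal prevalence.  Its category labels are illustrative; it makes no
claim to reproduce real survey joint distributions, survey weights, or
design effects (the real-data path is deliberately unweighted,
complete-case).

## What passing tests do and do not show

The generator emulates the *structure* of the study conditions (mediated
covariates, window-truncated multiplicative effects, a null variable, 192
unbalanced intersections).  It does not emulate real-data features such as
measurement error in the social variables, informative missingness, survey
design, or outcome misclassification, so method rankings here transfer to
real data only insofar as those features are ignorable.  Two documented
divergences from the published study conditions remain: the symmetric
effect-size sampler reproduces the stated truncation windows but not the
reported mean prevalences (see "Realised calibration"), and saturated-model
convergence proportions reflect this package's numerically stable fitter
rather than reference-GLM fragility.  Both are asserted honestly in the
acceptance suite rather than patched to pass.

## Known limitations

* Bayesian MAIHDA, survey weights, penalized regression, and
  discriminatory-accuracy outputs (ICC/AUC) are out of scope.
* CHAID omits the re-split step of the full Kass algorithm.
* CTree uses asymptotic test distributions; exact permutation inference at
  very small nodes is not implemented (node-size floors make this moot in
  the shipped scenarios).
* Tree methods carry no variance estimates, mirroring the methods
  themselves.
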