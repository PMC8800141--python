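# intersectprev

Simulation benchmark of methods that estimate the prevalence of a binary
health outcome within **social intersections** — subgroups defined by
crossing social position/identity categories (e.g. gender × ethnicity ×
age group × poverty).  Descriptive intersectional epidemiology needs
per-subgroup estimates for many, often small, intersections; this package
generates individual-level data with a *known* per-intersection prevalence
and measures how accurately nine analysis configurations recover it.

**Who it is for** — biostatisticians and epidemiologists comparing
analysis strategies for high-dimensional subgroup description of binary
outcomes, and anyone extending that comparison (new estimators, new
data-generating conditions).

## Methods compared

| method | idea |
|---|---|
| cross-classification | raw event proportion per intersection |
| main-effects regression | modified Poisson, no interactions (non-intersectional reference) |
| correctly specified regression | modified Poisson with the generating interactions |
| saturated regression | modified Poisson with all interactions |
| MAIHDA | logistic mixed model: fixed main effects + random intercept per intersection |
| CART | Gini tree, cost-complexity pruned by 10-fold CV |
| CTree | association-test splitting, Bonferroni-adjusted stopping (α = 0.05) |
| CHAID | chi-square splitting with Kass category merging (categorical inputs only) |
| random forest | 500 Gini trees, mtry tuned by out-of-bag Brier score |

"Modified Poisson" is Poisson regression with log link applied to a binary
outcome, paired with the robust sandwich covariance A⁻¹BA⁻¹ so the
coefficients are relative risks with valid inference.  MAIHDA (multilevel
analysis of individual heterogeneity and discriminatory accuracy) is fitted
as a frequentist binomial GLMM by Laplace-approximated maximum likelihood;
its empirical-Bayes intercepts shrink toward zero for small intersections.

## The data-generating process

Individuals carry six inputs.  In the *categorical* model X1 is uniform
over 4 categories and X6 over 3; in the *mixed* model X1 and X6 are
standard normal and are binned into sample quartiles/tertiles to form
intersections.  X2, X3, X5 are Bernoulli(0.2/0.5/0.25) and X4 is mediated
by X3 (P(X4=1|X3=0)=0.4, P(X4=1|X3=1)=0.7).  Crossing the categories gives
4·2·2·2·2·3 = **192 intersections**.  The outcome risk is log-linear, e.g.
for the categorical model

```
log P(Y=1) = β0 + β1.1[X1=1] + β1.2[X1=2] + β1.3[X1=3] + β2X2 + β3X3 + β4X4
             + β5X5 + β6[X1=2,X2=1] + β7[X1=3,X2=1] + β8·X3X4X5
```

with β0 = −3 (rare outcome) or −1.5 (common), X6 always null, and every
other effect drawn fresh each iteration from a normal centred at relative
risk 1 (SD 0.30) truncated to windows that exclude near-null effects
(rare: RR ∈ [0.20, 0.76] ∪ [1.24, 1.80]); a whole draw is rejected if it
could give any individual a probability above 1.

Accuracy is the **MAD ratio**

```
MAD = (1/n) Σᵢ |P̂ᵢ − Pᵢ| / p
```

over intersections i (equal weight per intersection), where Pᵢ is the true
prevalence from the generating formula, P̂ᵢ the method's estimate and p the
overall sample prevalence.  MAD = 0 only under perfect estimation of every
intersection.

## Worked example

Run one scaled-down scenario (rare outcome, categorical inputs, N = 2000,
20 iterations) and summarise:

```
$ intersectprev simulate --inputs categorical --tier rare --n 2000 \
      --reps 20 --seed 7 --methods cross_classification,main_effects,maihda,ctree \
      --out demo_store
wrote demo_store: 80 MAD rows, 15360 estimate rows

$ intersectprev evaluate --results demo_store
               scenario               method  count     mean      std      min      25%      50%      75%      max
rare/categorical/N=2000 cross_classification   20.0 1.290977 0.321201 0.788123 1.034658 1.305957 1.513682 1.831659
rare/categorical/N=2000                ctree   20.0 0.465527 0.109087 0.218804 0.404919 0.472910 0.541322 0.728612
rare/categorical/N=2000               maihda   20.0 0.330917 0.095077 0.197949 0.241323 0.333124 0.401535 0.509022
rare/categorical/N=2000         main_effects   20.0 0.331201 0.096127 0.198340 0.240218 0.331497 0.404549 0.508853
```

Read: at this small sample size the raw proportions (cross-classification)
miss each intersection's true prevalence by ~1.3× the overall prevalence on
average, the conditional-inference tree roughly halves that error, and
MAIHDA and the (mis-specified but low-variance) main-effects regression tie
at the bottom — MAIHDA's random-intercept variance shrinks to ≈ 0 here, so
it pools almost completely to its fixed effects.

Other entry points: `intersectprev fixture` writes a synthetic
blood-pressure survey-like table (60 intersections from sex/gender ×
race/ethnicity × age group × poverty, ~41% high-blood-pressure prevalence);
`intersectprev realdata` runs every applicable method on such a table,
defining the outcome as mean systolic ≥ 130 mmHg and/or mean diastolic
≥ 80 mmHg over up to three readings.  The same operations are available as
library functions (`simulate_dataset`, `fit_modified_poisson`,
`fit_maihda`, `fit_ctree`, `compute_mad`, `run_grid`, …).

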