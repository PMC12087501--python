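# Methods

## Problem and estimands

The package quantifies how much of the socioeconomic inequality in preterm
birth (PTB, gestation < 37 completed weeks) runs through four pregnancy
mediators — smoking, maternal mental ill health, hospitalisation for physical
health, and obstetric conditions — with area deprivation quintile (1 = most
deprived, 5 = least deprived, reference) as the exposure and maternal age
band, parity category and marital status as baseline confounders. Two
complementary mediation measures are implemented.

**Controlled direct effect (CDE) and proportion eliminated (PE).** Two
logistic regressions are fitted: Model 1 regresses PTB on exposure and
confounders (total-effect odds ratio), Model 2 adds the four mediators,
all exposure-by-mediator interactions and mediator-by-mediator interactions.
Because mediators are coded 0/1 with 0 = absent, the exposure main-effect OR
of Model 2 is the CDE at all mediators absent. The share of the inequality
removed by eliminating the mediators is

    PE = (OR_total − OR_CDE) / (OR_total − 1),

undefined when OR_total = 1. PE is computed from unrounded ORs; computing it
from ORs already rounded to two decimals gives a visibly different value
(e.g. inputs 1.26 and 1.21 give 0.192), which is expected behaviour of the
formula, not a defect.

**Interventional disparity measures (IDM) and proportion mediated (PM).**
The IDM asks how the standardised risk of PTB in quintile 1 would change if a
mediator's conditional distribution were shifted to that of quintile 5. Five
"richly specified" logistic models (all two-way interactions among each
model's predictors) encode the working DAG: smoking, mental health and
physical health depend on exposure + confounders and are conditionally
independent of each other; obstetric conditions additionally depend on the
three upstream mediators; the outcome depends on everything. Standardised
risks r(t, A) (outcome risk at exposure t with mediators in the set A drawn
as if exposure were the donor quintile) yield, on the absolute percentage-
point scale:

* TAA (total adjusted association) = r(1, ∅) − r(5, ∅)
* indirect_k = r(1, ∅) − r(1, {k}) for each mediator k
* direct = r(1, all four) − r(5, ∅)
* mediated dependence (MD) = TAA − direct − Σ indirect_k
* PM_k = indirect_k / TAA.

Additivity TAA = direct + Σ indirect + MD holds exactly by construction.
A shifted smoking distribution propagates into the obstetric-conditions draw,
so indirect_smoking includes the smoking → obstetric → PTB path.

## g-computation: Monte-Carlo and exact paths

`mc_standardize` expands each record in the standardisation population
`k_expansions` times (default 200, which suppresses Monte-Carlo error at the
first decimal of a percentage), draws the upstream mediators from their
fitted models, draws obstetric conditions conditional on the drawn values,
and averages the outcome model's predicted probability. The outcome is
averaged rather than drawn: the expectation is identical and the Monte-Carlo
variance strictly smaller; mediators must be drawn because downstream models
consume their realised values. Draws are pooled per unique covariate cell
(multinomial counts over the 8 upstream states, then binomial draws for
obstetric conditions), which has exactly the sampling distribution of
record-by-record simulation at a fraction of the cost.

Because every variable is discrete, the same estimand is computable exactly:
`enumerate_standardize` sums over all 2^4 mediator states per covariate
cell. It is the oracle in the test suite and the production fast path
(`k_expansions=0` / `method="enumerate"`).

Design choices made where the design was genuinely open:

* **Standardisation population**: the confounder distribution of the full
  cohort (configurable to the exposed quintile only). The full-cohort choice
  makes risks comparable across all contrasts.
* **Mediator-by-mediator interactions in Model 2**: all six pairwise
  products by default, consistent with the richly specified IDM models; a
  single smoking-by-obstetric term is available via
  `mediator_interactions="smoking_obstetric"`.
* **Exposure-by-mediator interactions** use the full five-level exposure
  factor.
* **Serial gestational-age contrasts** are binary logits of each category
  against term births only (no joint multinomial model); categories with
  fewer than two events in any quintile are skipped with a warning.

## Numerical choices

Binomial GLMs are fitted by IRLS (log-likelihood tolerance 1e-8, at most 100
iterations). Designs are collapsed to unique covariate patterns with
frequency weights before fitting — the likelihood is identical and fits are
orders of magnitude faster at large n. Fits showing non-convergence or
quasi-separation (non-finite or very large standard errors) fall back to a
small ridge penalty (alpha 1e-5) with a warning; penalised fits provide
predictions and point estimates but no standard errors. Percentile interval
bounds use the literal 1-based ranks ceil(0.025·N) and floor(0.975·N) of the
pooled sorted resample values (250 and 9750 when N = 10 000).

## Missing data

Smoking (binary), parity category and marital status are imputed by chained
equations: logistic models for binary, multinomial logistic for
multi-category variables; predictors are exposure, the fully observed
mediators and confounders, the binary PTB outcome (not the six-level
gestational-age category, to avoid outcome collinearity), the year, and the
current values of the other imputed variables. Draws are proper — model
coefficients are drawn from their asymptotic normal distribution before
values are sampled — so between-imputation variance is positive whenever
missingness is. Visit order is descending missingness (smoking, parity,
marital status); initial values are draws from observed marginals. Defaults
are 10 imputations of 10 iterations. Point estimates are pooled as
arithmetic means (log scale for ORs); intervals follow the
impute-once-then-resample-within-each-completed-dataset scheme rather than
re-imputing inside each resample.

## Resampling inference and E-values

`bootstrap_mi_ci` draws b resamples with replacement per completed dataset
(default 1000 × 10 datasets = 10 000 pooled values). `subsampling_ci`
resamples without replacement at size round(n^0.7) and reports raw
percentile bounds by default; these are conservative for an m-out-of-n
scheme, so an optional variant rescales percentile deviations by sqrt(m/n).
Per-dataset random substreams are spawned deterministically from the root
seed, so results are reproducible and independent of evaluation order.

E-values use E = RR + sqrt(RR(RR−1)) after converting the OR to a risk
ratio: identity conversion by default (the outcome is rare, ~6%), square
root conversion optionally. ORs below 1 are inverted first; a CI crossing 1
gives a CI-limit E-value of 1.

## Synthetic cohort generator

The generator emulates the structure of a national routine-maternity cohort:
five-quintile exposure with the published population shares; per-quintile
confounder distributions taken from the published descriptive table
(normalised over observed categories); logistic mediator/outcome models in
the DAG order above. Intercept and exposure offsets are calibrated by exact
moment matching (per-quintile root finding over the enumerated covariate
space) so that per-quintile prevalences reproduce the published margins
(smoking 22.6 → 6.8%, mental health 4.7 → 2.6%, physical health 12.8 →
9.8%, obstetric conditions 25.9 → 21.7%, preterm 6.9 → 5.2% across
quintiles 1 → 5). Non-exposure coefficients are fixed plausible log-odds
ratios (e.g. smoking→PTB log 1.5, obstetric→PTB log 2.0, physical→obstetric
0.5); they are conventions of the synthetic mechanism, not estimates.

Gestational age within the preterm stratum is uniform over 22–36 weeks and
categorical over 37–43 on the term side (weights 0.10/0.15/0.25/0.30/0.15/
0.04/0.01); the routine-data sources the cohort emulates do not pin these
down, so the weights are declared defaults, configurable. Year is uniform
over 2000–2019 with no mediator-year trends. Birthweight, maternal age
within band and parity counts are filled so every generated record passes
the inclusion filters. Missingness is injected MAR with per-quintile rates
calibrated to the published missing fractions (marginals 32.9% smoking,
16.1% parity, 1.6% marital status), depending only on exposure and year.

All draws flow from one root generator in a fixed substream order
(exposure → confounders → upstream mediators → obstetric → outcome →
gestation week → auxiliary fields), so a seed reproduces a cohort exactly.

Because the covariate/mediator space is finite (5 × 48 confounder cells ×
2^4 mediator states), `true_estimands` computes every IDM component, the
standardised total OR and the generating CDE by exact enumeration — zero
Monte-Carlo error — enabling parameter-recovery tests against known truth.
Named scenarios (`null`, `direct_only`, `smoking_only`,
`obstetric_dependent`, `mixed`) give mechanisms with qualitatively known
answers (e.g. full mediation through smoking forces CDE = 1 and PM_smoking
= 1 exactly).

**What the generator does not emulate**: the joint dependence of confounders
beyond per-quintile marginals, day-level gestation, secular trends,
non-singleton or non-live births (generated records all pass inclusion; the
filters are exercised by dedicated fixtures), MNAR mechanisms, and any
within-quintile geographic structure. Passing recovery tests therefore shows
the estimators are correct under the stated DAG and logistic mechanism, not
that the substantive published estimates are right.

## Problem sizes used in tests and the acceptance script

Parameter-recovery tests use cohorts of n = 200 000 with exact-enumeration
decomposition; the oracle-equivalence grid fits models at n = 4000 and
compares Monte-Carlo (k = 10 000) to enumeration within 3 Monte-Carlo SEs;
imputation checks use n = 20 000 with m = 3; bootstrap coverage uses 500
replicates of n = 2000 with b = 1000. The acceptance script analyses one
synthetic cohort of n = 150 000 with m = 5 imputations (10 iterations) and
k = 200 expansions. These sizes give Monte-Carlo error comfortably inside
the assertion tolerances while keeping a full run fast on one CPU.

## Known limitations

* IDM identification assumes no unmeasured mediator-outcome confounding;
  the synthetic mechanism satisfies it by construction, real data need not.
* Natural direct/indirect effects are deliberately not implemented (they
  require cross-world assumptions the interventional measures avoid).
* Raw-percentile subsampling intervals are conservative; the rate-corrected
  variant is provided but off by default to match the primary scheme.
* The recovery-test tolerance uses a conservative closed-form SE for a
  standardised risk difference; it bounds, rather than estimates, the
  sampling error of model-based decomposition components.
* Penalised fallback fits have no covariance, so Wald CIs are unavailable
  for them; resampling intervals remain valid.
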