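# Methods

## Data-generating model

Each simulated subject carries one standardized covariate X (population
mean 0, variance 1), a binary treatment T and a binary outcome Y:

    logit P(T = 1 | X = x) = β₀ + β₁ x,          β₁ ≥ 0
    logit P(Y = 1 | T, X = x) = γ₀ + log(OR) · T + x

The covariate coefficient in the outcome model is fixed at 1, so OR is the
*conditional* treatment odds ratio. A single covariate is enough here
because matching operates on the scalar propensity score: X stands for the
linear predictor of any multi-covariate model, and the three families span
the propensity-score shapes that matter —

* `unimodal`: standard normal;
* `categorical`: 10 support points (k − 5.5)/√(59/12), k = 1..10, with
  probabilities (1,2,3,4,5,5,4,3,2,1)/30. This family deliberately produces
  exactly tied propensity scores;
* `multimodal`: ½N(−2τ, τ²) + ½N(2τ, τ²) with τ = 1/√5, the unique value
  giving total variance τ² + (2τ)² = 1.

## Calibration

Scenario targets are the treated fraction p_g = E[P(T=1|X)], the
propensity-model c-statistic, and the marginal event rate
p_e = E[P(Y=1|T,X)]. All three are solved by deterministic root-finding
against *exact* expectations over the covariate law — the 10 atoms for the
categorical family, a 4001-point normalized trapezoid grid of the density
for the continuous ones — so no sampling noise enters the data-generating
process itself. Brent's method with xtol 1e−12 leaves the targets met far
inside the documented 1e−4 tolerance.

The c-statistic is P(score_T > score_C) + ½P(score_T = score_C), the
standard concordance with half-weight ties (the categorical family forces a
tie convention; half weight is the usual one). Because it is strictly
increasing in β₁ at fixed prevalence, and prevalence is strictly increasing
in β₀ at fixed slope, the calibration nests two monotone 1-D solves:
intercept for prevalence inside slope for concordance. A concordance target
the family cannot reach (ties bound the categorical family away from 1
whenever the treatment threshold falls inside an atom) raises an error
reporting the attainable supremum. The outcome intercept γ₀ is a third
monotone solve of E[p(x)·expit(γ₀+logOR+x) + (1−p(x))·expit(γ₀+x)] = p_e.

Seeding: a master seed feeds `numpy` `SeedSequence` substreams salted by
purpose (cohort draw, replicate order k, data addition, addition re-order),
so changing the number of replicates K never perturbs the cohort draw, and
every artifact is bit-reproducible from its recorded seed.

## Matching

Matching runs on the *fitted* logit propensity (logistic MLE of T on X, as
in practice; true scores are kept for diagnostics only). The caliper is a
fraction (default 0.25, alternative 0.15) of the pooled sample SD (ddof 1)
of the logit score over all subjects. Greedy assignment without
replacement under four orders; ties are resolved deterministically, which
matters because the categorical family guarantees exact ties:

* HtoL / LtoH order treated by descending/ascending score, equal scores by
  ascending subject index;
* equidistant controls: lower logit score first, then lower index;
* Clos repeatedly takes the globally closest (treated, control) pair,
  breaking exact ties lexicographically on (treated index, control index);
* Rand permutes the treated uniformly from its own substream.

1:2 matching runs two whole-cohort passes in the same order: pass 1 equals
the 1:1 result, pass 2 hands out second controls from the remaining pool.
Treated subjects unmatched after pass 1 are dropped; sets left with a
single control are retained (variable ratio). This two-pass convention
keeps the first-pass sets identical to 1:1 matching; whether best-match
ordering should instead interleave second controls into the first pass is
genuinely open, and the two-pass form was chosen for that property.

A quadratic-scan oracle (`brute_force_match_oracle`, N ≤ 50) re-implements
the same contract independently; the test suite holds the production
matcher to exact agreement with it across thousands of random instances,
including tied-score ones.

## Estimation and inference

The outcome analysis is logistic regression of Y on T over the matched (or
weighted) sample. That model is saturated in the two arms, so the MLE
equals the 2×2-table odds ratio and the model SE equals
√(1/a + 1/b + 1/c + 1/d); the closed form is used when all cells are
positive, and separated tables are fitted by capped Fisher scoring
(100 iterations, tol 1e−8) and *retained* with their huge SEs — the
proportion of fits with model SE > 100 is itself a study endpoint, so
divergence must be recorded, not raised. Estimates are flagged `unstable`
when non-convergent or when the model SE exceeds 100.

Robust variances are CR2: on the IRLS working representation (U = W^½X,
transformed residuals), each cluster's residuals are premultiplied by the
symmetric inverse square root of (I − U_c(U'U)⁻¹U_c'), making the sandwich
exactly unbiased under the working model; matched sets are the clusters
(singletons for weighted fits, where CR2 reduces to HC2). The robust CI
uses a t quantile with Bell–McCaffrey/Satterthwaite degrees of freedom; the
model-based CI uses the normal quantile. A numerically singular adjustment
falls back to CR1 scaling with a warning and flag.

Weighting comparators use the fitted propensity e: ATT (treated 1, control
e/(1−e)); truncated ATT, zeroing subjects with e above the type-7 95th
percentile of all fitted e; overlap weights (1−e / e), which exactly
balance the covariate mean across arms under a logistic fit. The weighted
model SE comes from the weighted information matrix and the robust SE from
the singleton-cluster sandwich with weights in bread and meat (treating
them as precision rather than frequency weights — the natural reading for
these estimands).

## Instability metrics

For one dataset: K = 100 random-order matchings (configurable; 100 keeps
the 486-cell study tractable and, by analogy with multiple imputation,
loses little precision), each yielding an odds ratio. The *width* is the
type-7 97.5th − 2.5th percentile of the stable replicate estimates — the
cherry-pickable span. *M_Med* is their median; its CI is read off the
replicate whose estimate is nearest the median (lowest index on ties),
since an interpolated even-K median is attained by no replicate. *M_Med2*
keeps the M_Med point estimate but uses the multiple-outputation variance

    V = mean(within-replicate CR2 variance) − (1 − 1/K) · var(log ÔR_k)

floored at 1% of the mean within variance. The between-variance subtraction
follows the multiple-outputation idea of removing the resampling noise
shared across replicates; the floor guards the sparse cells where the
between term transiently dominates. Unstable replicates are excluded from
the width percentiles and the median, and reported as a count.

*Data-addition drift*: draw ⌈0.1N⌉ new subjects from the same calibrated
population, merge, refit the propensity model, recompute the caliper,
rematch with each method, and report |OR_merged − OR_original|. Rand uses a
fresh substream by default — a re-analysis after data accrual has no
obligation to reuse the old seed, and even a reused seed permutes a
different treated set — with a reuse mode and a frozen-propensity
diagnostic mode available.

## Simulation study

The factorial grid has 486 cells; each cell is summarized per method by
median bias (median ÔR − OR, on the OR scale), IQR of ÔR, median width
(random-order methods), median drift, model and robust CI coverage of the
conditional OR, the unstable proportion, and median SEs. Unstable
estimates stay in the bias/IQR aggregates (medians are robust to them) but
leave the SE summaries; coverage counts every CI, including the effectively
infinite ones from separated fits, which is what makes sparse-cell
model-based coverage "conservative". The batch driver checkpoints one CSV
row per (scenario, method) and derives each scenario's seed from the master
seed and the scenario id, so interrupted and resumed runs coincide with
uninterrupted ones.

Replication sizes: the package defaults to 1,000 simulations per cell for
full runs. The acceptance script and test suite use desk-scale profiles —
200 datasets × K = 100 for the width sweep, 500 for the sparse-cell
instability bound, 1,000 for benign-cell coverage, 300 × K = 50 for the
M_Med check — sizes at which the reported quantities are stable to well
within their documented tolerances.

## What the simulator does and does not emulate

It reproduces the study conditions exactly: controlled treated fraction,
propensity c-statistic, event rate, conditional OR, and the three
propensity-score shapes. It does not emulate multi-covariate confounding
structure (X is the composite linear predictor), covariate measurement
error, unmeasured confounders, missingness, or non-binary outcomes. Passing
tests therefore certify the matching/estimation machinery and the
instability phenomenology under these shapes — not robustness of any
substantive analysis to violations the generator does not model.

## Known limitations

* Survival and continuous outcomes are out of scope; so are
  sparse-data bias corrections, optimal/full matching, matching with
  replacement, and machine-learning propensity models.
* The odds ratio is non-collapsible: bias and coverage are judged against
  the conditional OR by convention, and the matched/weighted estimands are
  marginal over their respective populations, so a small systematic gap at
  strong covariate effects is expected rather than a defect.
* The multiple-outputation SE uses the (1 − 1/K) between-variance factor
  with a 1% floor; other variants of the median modification exist, and the
  exact choice matters only when the between term rivals the within term.
* The CR2 Satterthwaite df treats transformed working errors as
  homoskedastic, the standard Bell–McCaffrey assumption.
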