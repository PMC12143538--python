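"""Instability diagnostics for random-order caliper matching.

Replicating the random-order matching many times on one dataset exposes how
much of the reported odds ratio is an artifact of the (cherry-pickable)
matching order.  This module provides

* K-fold random-order replication with independent substreams,
* the width diagnostic (97.5th minus 2.5th percentile of the K replicate
  odds ratios — the span available to cherry-picking),
* the median-of-matchings estimator M_Med (median of the K odds ratios, with
  a CI read off the replicate whose estimate sits nearest the median) and its
  multiple-outputation variant M_Med2,
* the data-addition drift experiment: append 10% more subjects drawn from
  the same population, redo the whole analysis, and record the absolute
  change in the odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import Cohort, ScenarioConfig, generate_cohort, _calibrated_models
from .estimation import EffectEstimate, estimate_or_matched
from .matching import MatchSpec, PropensityFit, fit_propensity, greedy_match

__all__ = [
    "StabilityReport",
    "replicate_random_matching",
    "width",
    "mmed",
    "mmed2_se",
    "data_addition_drift",
    "stability_report",
]

# substream salts: keep cohort draws, matching orders and data additions on
# independent streams so e.g. changing K never perturbs the cohort itself
_SALT_REPLICATE = 0xA1
_SALT_ADDITION = 0xA2
_SALT_ADDITION_ORDER = 0xA3


@dataclass
class StabilityReport:
    """Replicate-width and median-of-matchings summary for one dataset."""

    estimates: list[EffectEstimate]
    width: float
    mmed_or: float
    mmed_ci: tuple[float, float]
    mmed2_se: float
    n_unstable: int
    k: int


def replicate_random_matching(
    cohort: Cohort,
    spec: MatchSpec,
    K: int,
    master_seed: int,
    ps: PropensityFit | None = None,
    robust: bool = False,
) -> list[EffectEstimate]:
    """K random-order matching runs of one dataset, one estimate each.

    The propensity model is fitted once (the order varies, the scores do
    not); replicate k consumes substream (master_seed, k) so the vector of
    estimates is reproducible and extending K only appends replicates.
    """
    if spec.order != "Rand":
        raise ValueError("replication is defined for the Rand order")
    if K < 1:
        raise ValueError("K must be >= 1")
    if ps is None:
        ps = fit_propensity(cohort)
    out: list[EffectEstimate] = []
    for k in range(K):
        sub = int(np.random.default_rng(
            np.random.SeedSequence([int(master_seed), _SALT_REPLICATE, k])
        ).integers(0, 2**31 - 1))
        rspec = MatchSpec(order="Rand", ratio=spec.ratio,
                          caliper_fraction=spec.caliper_fraction, rng_seed=sub)
        ms = greedy_match(ps.logit_ps, cohort.treatment, rspec)
        if ms.n_matched_treated == 0:
            est = EffectEstimate(
                or_hat=np.nan, log_or=np.nan, se_model=np.inf, se_robust=np.nan,
                ci_model=(0.0, np.inf), ci_robust=(np.nan, np.nan), df_robust=np.nan,
                converged=False, unstable=True, method="M_Rand", n_subjects=0,
            )
        else:
            est = estimate_or_matched(cohort, ms, robust=robust)
            est.method = "M_Rand"
        out.append(est)
    return out


def _stable_ors(estimates: list[EffectEstimate]) -> np.ndarray:
    return np.array([e.or_hat for e in estimates if e.stable])


def width(estimates: list[EffectEstimate] | np.ndarray,
          lo: float = 2.5, hi: float = 97.5) -> float:
    """97.5th minus 2.5th percentile of the replicate odds ratios.

    Type-7 (linear interpolation) quantiles on the OR scale; unstable
    replicates are excluded.  Returns nan when fewer than two stable
    replicates remain.
    """
    if len(estimates) and isinstance(estimates[0], EffectEstimate):
        ors = _stable_ors(estimates)
    else:
        ors = np.asarray(estimates, dtype=float)
        ors = ors[np.isfinite(ors)]
    if ors.size < 2:
        return np.nan
    p_lo, p_hi = np.percentile(ors, [lo, hi])
    return float(p_hi - p_lo)


def mmed(estimates: list[EffectEstimate]) -> tuple[float, int]:
    """Median of the K replicate odds ratios and the median-attaining replicate.

    Returns ``(median OR, index)`` where ``index`` selects the replicate whose
    estimate is nearest the median (lowest index on ties); its matched data
    supply the M_Med confidence interval.
    """
    ors = np.array([e.or_hat for e in estimates])
    stable = np.array([e.stable for e in estimates])
    if not stable.any():
        raise ValueError("no stable replicate to take a median over")
    med = float(np.median(ors[stable]))
    dist = np.where(stable, np.abs(ors - med), np.inf)
    return med, int(np.argmin(dist))


def mmed2_se(estimates: list[EffectEstimate],
             within_variances: np.ndarray | None = None,
             floor_frac: float = 0.01) -> float:
    """Multiple-outputation standard error for the median-of-matchings estimate.

    V = mean(within) - (1 - 1/K) * var(between log-estimates), floored at
    ``floor_frac`` times the mean within-replicate variance so the between
    correction can never drive the variance to zero or below.  Within
    variances default to the replicates' CR2 robust variances (log-OR scale).
    """
    stable = [e for e in estimates if e.stable]
    if len(stable) < 2:
        return np.nan
    if within_variances is None:
        wv = np.array([e.se_robust ** 2 for e in stable])
    else:
        wv = np.asarray(within_variances, dtype=float)
        wv = wv[np.isfinite(wv)]
    wv = wv[np.isfinite(wv)]
    if wv.size == 0:
        return np.nan
    K = len(stable)
    between = float(np.var([e.log_or for e in stable], ddof=1))
    mean_within = float(np.mean(wv))
    v = mean_within - (1.0 - 1.0 / K) * between
    v = max(v, floor_frac * mean_within)
    return float(np.sqrt(v))


def stability_report(
    cohort: Cohort,
    spec: MatchSpec,
    K: int = 100,
    master_seed: int = 0,
    robust: bool = True,
    ps: PropensityFit | None = None,
) -> StabilityReport:
    """Full one-dataset diagnostic: K replicates, width, M_Med, M_Med2."""
    reps = replicate_random_matching(cohort, spec, K, master_seed, ps=ps, robust=robust)
    n_unstable = sum(1 for e in reps if not e.stable)
    w = width(reps)
    try:
        med, sel = mmed(reps)
        ci = reps[sel].ci_robust if robust else reps[sel].ci_model
    except ValueError:
        med, ci = np.nan, (np.nan, np.nan)
    se2 = mmed2_se(reps) if robust else np.nan
    return StabilityReport(
        estimates=reps, width=w, mmed_or=med, mmed_ci=ci,
        mmed2_se=se2, n_unstable=n_unstable, k=K,
    )


def _single_estimate(cohort: Cohort, ps: PropensityFit, spec: MatchSpec,
                     robust: bool = False) -> EffectEstimate | None:
    ms = greedy_match(ps.logit_ps, cohort.treatment, spec)
    if ms.n_matched_treated == 0:
        return None
    return estimate_or_matched(cohort, ms, robust=robust)


def data_addition_drift(
    cohort: Cohort,
    cfg: ScenarioConfig,
    methods: list[MatchSpec],
    add_fraction: float = 0.1,
    seed: int = 0,
    refit_ps: bool = True,
    fresh_rand_stream: bool = True,
) -> dict[str, float]:
    """Absolute odds-ratio change after appending ``add_fraction`` new subjects.

    New subjects are drawn from the same calibrated population, the merged
    dataset is re-analyzed from scratch (propensity refit, caliper
    recomputed, re-matched), and |OR_merged - OR_original| is returned per
    method.  Rand uses a fresh substream by default, emulating an analyst
    re-running the pipeline; set ``fresh_rand_stream=False`` to reuse the
    original seed.  ``refit_ps=False`` freezes the original propensity model
    (diagnostic mode).  Unstable analyses yield nan for that method.
    """
    n_add = int(np.ceil(add_fraction * cohort.n))
    ps0 = fit_propensity(cohort)
    if n_add == 0:
        merged = cohort
    else:
        models = _calibrated_models(cfg)
        add_seed = int(np.random.default_rng(
            np.random.SeedSequence([int(seed), _SALT_ADDITION])
        ).integers(0, 2**31 - 1))
        extra = generate_cohort(cfg, add_seed, models=models, n=n_add)
        merged = Cohort(
            covariate=np.concatenate([cohort.covariate, extra.covariate]),
            treatment=np.concatenate([cohort.treatment, extra.treatment]),
            outcome=np.concatenate([cohort.outcome, extra.outcome]),
            true_propensity=np.concatenate([cohort.true_propensity, extra.true_propensity]),
            seed_record=cohort.seed_record,
        )
    if refit_ps:
        ps1 = fit_propensity(merged)
    else:
        lp = ps0.fit.linear_predictor(
            np.column_stack([np.ones(merged.n), merged.covariate])
        )
        ps1 = PropensityFit(logit_ps=lp, params=ps0.params,
                            converged=ps0.converged, fit=ps0.fit)

    drift: dict[str, float] = {}
    for spec in methods:
        name = spec.order if spec.caliper_fraction is not None else f"{spec.order}_NoCal"
        spec0 = spec
        spec1 = spec
        if spec.order == "Rand":
            base = spec.rng_seed if spec.rng_seed is not None else 0
            spec0 = MatchSpec("Rand", spec.ratio, spec.caliper_fraction, rng_seed=base)
            if fresh_rand_stream:
                new_seed = int(np.random.default_rng(
                    np.random.SeedSequence([int(seed), _SALT_ADDITION_ORDER])
                ).integers(0, 2**31 - 1))
                spec1 = MatchSpec("Rand", spec.ratio, spec.caliper_fraction, rng_seed=new_seed)
            else:
                spec1 = spec0
        e0 = _single_estimate(cohort, ps0, spec0)
        e1 = _single_estimate(merged, ps1, spec1)
        if e0 is None or e1 is None or not (e0.stable and e1.stable):
            drift[name] = np.nan
        else:
            drift[name] = float(abs(e1.or_hat - e0.or_hat))
    return drift
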