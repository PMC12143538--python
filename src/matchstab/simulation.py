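"""Factorial Monte-Carlo study of matching-order instability.

Enumerates the scenario grid (3 covariate families x 3 treated fractions x
2 c-statistics x 3 event rates x 3 odds ratios x 3 sample sizes = 486
cells), runs the requested estimators on each simulated dataset, and
aggregates the metric suite: median bias and IQR of the odds ratios,
median replicate width, median data-addition drift, coverage probabilities
of model-based and robust CIs, and the proportion of highly unstable
estimates (model-based log-OR SE above 100).

Bias and coverage are measured against the conditional odds ratio of the
data-generating model; the odds ratio being non-collapsible, this is a
convention, not a correction.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats as _stats

from .cohorts import ScenarioConfig, CovariateSpec, generate_cohort, _calibrated_models
from .estimation import (
    EffectEstimate,
    UNSTABLE_SE_THRESHOLD,
    compute_weights,
    estimate_or_matched,
    estimate_or_weighted,
)
from .matching import MatchSpec, fit_propensity, greedy_match
from .stability import data_addition_drift, mmed, mmed2_se, replicate_random_matching, width

__all__ = [
    "ALL_METHODS",
    "GridMetrics",
    "enumerate_grid",
    "run_scenario",
    "unstable_proportion",
    "run_grid",
    "RESULTS_SCHEMA_VERSION",
]

log = logging.getLogger("matchstab")

ALL_METHODS = (
    "M_Rand", "M_HtoL", "M_LtoH", "M_Clos", "M_NoCal",
    "W_ATT", "W_ATTt", "W_ATO", "M_Med", "M_Med2",
)
_MATCH_ORDERS = {"M_HtoL": "HtoL", "M_LtoH": "LtoH", "M_Clos": "Clos"}
_WEIGHT_KINDS = {"W_ATT": "ATT", "W_ATTt": "ATT_trunc95", "W_ATO": "ATO"}

_GRID_LEVELS = {
    "covariate": ("unimodal", "categorical", "multimodal"),
    "pg": (0.1, 0.2, 0.4),
    "c": (0.6, 0.85),
    "pe": (0.1, 0.3, 0.5),
    "true_or": (0.5, 0.75, 1.0),
    "n": (100, 200, 400),
}

RESULTS_SCHEMA_VERSION = 1

RESULTS_COLUMNS = [
    "schema", "scenario_id", "covariate", "pg", "c", "pe", "true_or", "n",
    "ratio", "caliper_fraction", "method", "n_sims", "k", "seed",
    "median_or", "median_bias", "iqr", "median_width", "median_drift",
    "cp_model", "cp_robust", "prop_unstable",
    "median_se_model", "median_se_robust",
]


@dataclass
class GridMetrics:
    """Aggregated metrics for one (scenario, method) cell.

    Metrics a method does not define (e.g. replicate width for deterministic
    orders) are nan sentinels, never silent zeros.
    """

    scenario: ScenarioConfig
    method: str
    n_sims: int
    median_or: float = np.nan
    median_bias: float = np.nan
    iqr: float = np.nan
    median_width: float = np.nan
    median_drift: float = np.nan
    cp_model: float = np.nan
    cp_robust: float = np.nan
    prop_unstable: float = np.nan
    median_se_model: float = np.nan
    median_se_robust: float = np.nan


def scenario_id(cfg: ScenarioConfig) -> str:
    cal = "none" if cfg.caliper_fraction is None else f"{cfg.caliper_fraction:g}"
    return (f"{cfg.covariate.family}|pg{cfg.pg:g}|c{cfg.c_target:g}|pe{cfg.pe:g}"
            f"|or{cfg.true_or:g}|n{cfg.n}|r{cfg.ratio}|cal{cal}")


def enumerate_grid(
    covariate=None, pg=None, c=None, pe=None, true_or=None, n=None,
    ratio: int = 1, caliper_fraction: float | None = 0.25,
) -> list[ScenarioConfig]:
    """Full factorial scenario grid in canonical order, optionally filtered.

    The canonical order iterates covariate family, then pg, c, pe, OR and N
    (slowest to fastest).  Filter arguments accept a single value or an
    iterable of values; an empty result raises.
    """
    def _levels(name, flt):
        levels = _GRID_LEVELS[name]
        if flt is None:
            return levels
        if isinstance(flt, (str, int, float)):
            flt = (flt,)
        chosen = tuple(v for v in levels if v in set(flt))
        return chosen

    axes = {k: _levels(k, v) for k, v in
            zip(_GRID_LEVELS, (covariate, pg, c, pe, true_or, n))}
    out = [
        ScenarioConfig(
            covariate=CovariateSpec(fam), pg=pgv, c_target=cv, pe=pev,
            true_or=orv, n=nv, ratio=ratio, caliper_fraction=caliper_fraction,
        )
        for fam, pgv, cv, pev, orv, nv in itertools.product(*axes.values())
    ]
    if not out:
        raise ValueError("scenario filter selected no grid cells")
    return out


def unstable_proportion(estimates: list[EffectEstimate]) -> float:
    """Fraction of estimates with model-based log-OR SE > 100 or non-convergence."""
    if not estimates:
        return 0.0
    flagged = sum(
        1 for e in estimates
        if (not e.converged) or (not np.isfinite(e.se_model))
        or e.se_model > UNSTABLE_SE_THRESHOLD
    )
    return flagged / len(estimates)


def _covers(ci: tuple[float, float], target: float) -> bool:
    lo, hi = ci
    return bool(lo <= target <= hi)   # nan endpoints compare False


def _sim_seed(master_seed: int, sim: int) -> int:
    return int(np.random.default_rng(
        np.random.SeedSequence([int(master_seed), 0x51, sim])
    ).integers(0, 2**31 - 1))


def run_scenario(
    cfg: ScenarioConfig,
    methods: tuple[str, ...] = ("M_Rand", "M_LtoH", "M_Clos"),
    n_sims: int = 1000,
    K: int = 100,
    master_seed: int = 0,
    robust: bool = False,
    compute_drift: bool = False,
    width_methods: tuple[str, ...] = ("M_Rand",),
) -> dict[str, GridMetrics]:
    """Monte-Carlo metrics for one grid cell, per method.

    Replicate widths are computed for methods in ``width_methods`` (when K
    >= 2); M_Med / M_Med2 reuse the M_Rand replicates.  ``robust`` switches
    on CR2 CIs (needed for robust-coverage metrics, off by default for
    speed).  The run is fully reproducible from ``master_seed``.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    models = _calibrated_models(cfg)
    need_reps = bool(
        {"M_Med", "M_Med2"} & set(methods)
        or ("M_Rand" in methods and "M_Rand" in width_methods and K >= 2)
    )
    need_reps_robust = robust and "M_Med2" in methods

    per_method: dict[str, list[EffectEstimate]] = {m: [] for m in methods}
    widths: dict[str, list[float]] = {m: [] for m in width_methods if m in methods}
    drifts: dict[str, list[float]] = {}

    for sim in range(n_sims):
        seed = _sim_seed(master_seed, sim)
        cohort = generate_cohort(cfg, seed, models=models)
        if cohort.treatment.sum() in (0, cohort.n):
            continue        # degenerate draw: no treated or no controls
        ps = fit_propensity(cohort)

        reps = None
        if need_reps:
            reps = replicate_random_matching(
                cohort, MatchSpec("Rand", cfg.ratio, cfg.caliper_fraction),
                K=K, master_seed=seed, ps=ps, robust=need_reps_robust,
            )

        for m in methods:
            est = None
            if m == "M_Rand":
                if reps is not None:
                    est = reps[0]
                    if robust and not need_reps_robust and est.stable:
                        est = _rand_single(cohort, ps, cfg, seed, robust=True)
                else:
                    est = _rand_single(cohort, ps, cfg, seed, robust=robust)
                if m in widths and reps is not None:
                    widths[m].append(width(reps))
            elif m in _MATCH_ORDERS:
                spec = MatchSpec(_MATCH_ORDERS[m], cfg.ratio, cfg.caliper_fraction)
                est = _matched_estimate(cohort, ps, spec, robust)
            elif m == "M_NoCal":
                spec = MatchSpec("Rand", cfg.ratio, None, rng_seed=seed)
                est = _matched_estimate(cohort, ps, spec, robust)
                if m in widths:
                    nreps = replicate_random_matching(
                        cohort, MatchSpec("Rand", cfg.ratio, None),
                        K=K, master_seed=seed, ps=ps, robust=False,
                    )
                    widths[m].append(width(nreps))
            elif m in _WEIGHT_KINDS:
                e = expit(ps.logit_ps)
                e = np.clip(e, 1e-12, 1 - 1e-12)
                ws = compute_weights(e, cohort.treatment, _WEIGHT_KINDS[m])
                try:
                    est = estimate_or_weighted(cohort, ws, robust=robust)
                except ValueError:
                    est = None
                if est is not None:
                    est.method = m
            elif m in ("M_Med", "M_Med2"):
                est = _mmed_estimate(reps, robust and m == "M_Med2", m)
            if est is not None:
                est.method = m
                per_method[m].append(est)

        if compute_drift:
            specs = []
            for m in methods:
                if m in _MATCH_ORDERS:
                    specs.append(MatchSpec(_MATCH_ORDERS[m], cfg.ratio, cfg.caliper_fraction))
                elif m == "M_Rand":
                    specs.append(MatchSpec("Rand", cfg.ratio, cfg.caliper_fraction, rng_seed=seed))
                elif m == "M_NoCal":
                    specs.append(MatchSpec("Rand", cfg.ratio, None, rng_seed=seed))
            d = data_addition_drift(cohort, cfg, specs, seed=seed)
            for key, val in d.items():
                name = {"HtoL": "M_HtoL", "LtoH": "M_LtoH", "Clos": "M_Clos",
                        "Rand": "M_Rand", "Rand_NoCal": "M_NoCal"}.get(key, key)
                drifts.setdefault(name, []).append(val)

    return {
        m: _aggregate(cfg, m, per_method[m], widths.get(m), drifts.get(m), robust)
        for m in methods
    }


def _rand_single(cohort, ps, cfg, seed, robust) -> EffectEstimate | None:
    sub = int(np.random.default_rng(
        np.random.SeedSequence([int(seed), 0xA1, 0])
    ).integers(0, 2**31 - 1))
    spec = MatchSpec("Rand", cfg.ratio, cfg.caliper_fraction, rng_seed=sub)
    return _matched_estimate(cohort, ps, spec, robust)


def _matched_estimate(cohort, ps, spec, robust) -> EffectEstimate | None:
    ms = greedy_match(ps.logit_ps, cohort.treatment, spec)
    if ms.n_matched_treated == 0:
        return None
    return estimate_or_matched(cohort, ms, robust=robust)


def _mmed_estimate(reps, robust, name) -> EffectEstimate | None:
    if reps is None:
        raise ValueError(f"{name} requires random-order replicates (K >= 1)")
    try:
        med, sel = mmed(reps)
    except ValueError:
        return None
    base = reps[sel]
    est = EffectEstimate(
        or_hat=med, log_or=float(np.log(med)), se_model=base.se_model,
        se_robust=base.se_robust, ci_model=base.ci_model, ci_robust=base.ci_robust,
        df_robust=base.df_robust, converged=base.converged, unstable=base.unstable,
        method=name, n_subjects=base.n_subjects,
    )
    if name == "M_Med2" and robust:
        se2 = mmed2_se(reps)
        if np.isfinite(se2):
            z = _stats.norm.ppf(0.975)
            est.se_robust = se2
            est.ci_robust = (float(np.exp(est.log_or - z * se2)),
                             float(np.exp(est.log_or + z * se2)))
            est.df_robust = np.nan
    return est


def _aggregate(cfg, method, ests, width_list, drift_list, robust) -> GridMetrics:
    gm = GridMetrics(scenario=cfg, method=method, n_sims=len(ests))
    if not ests:
        return gm
    ors = np.array([e.or_hat for e in ests])
    finite = ors[np.isfinite(ors)]
    if finite.size:
        gm.median_or = float(np.median(finite))
        gm.median_bias = gm.median_or - cfg.true_or
        q1, q3 = np.percentile(finite, [25, 75])
        gm.iqr = float(q3 - q1)
    gm.prop_unstable = unstable_proportion(ests)
    gm.cp_model = float(np.mean([_covers(e.ci_model, cfg.true_or) for e in ests]))
    if robust:
        rcis = [e.ci_robust for e in ests if np.isfinite(e.se_robust)]
        if rcis:
            gm.cp_robust = float(np.mean([_covers(ci, cfg.true_or) for ci in rcis]))
    se_m = np.array([e.se_model for e in ests if e.stable])
    if se_m.size:
        gm.median_se_model = float(np.median(se_m))
    se_r = np.array([e.se_robust for e in ests
                     if e.stable and np.isfinite(e.se_robust)])
    if se_r.size:
        gm.median_se_robust = float(np.median(se_r))
    if width_list:
        wl = np.asarray(width_list, dtype=float)
        wl = wl[np.isfinite(wl)]
        if wl.size:
            gm.median_width = float(np.median(wl))
    if drift_list:
        dl = np.asarray(drift_list, dtype=float)
        dl = dl[np.isfinite(dl)]
        if dl.size:
            gm.median_drift = float(np.median(dl))
    return gm


# ---------------------------------------------------------------------------
# batch driver

def _scenario_seed(base_seed: int, sid: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{sid}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _metrics_row(gm: GridMetrics, sid: str, K: int, seed: int) -> dict:
    cfg = gm.scenario
    return {
        "schema": RESULTS_SCHEMA_VERSION,
        "scenario_id": sid,
        "covariate": cfg.covariate.family,
        "pg": cfg.pg, "c": cfg.c_target, "pe": cfg.pe,
        "true_or": cfg.true_or, "n": cfg.n, "ratio": cfg.ratio,
        "caliper_fraction": np.nan if cfg.caliper_fraction is None else cfg.caliper_fraction,
        "method": gm.method, "n_sims": gm.n_sims, "k": K, "seed": seed,
        "median_or": gm.median_or, "median_bias": gm.median_bias, "iqr": gm.iqr,
        "median_width": gm.median_width, "median_drift": gm.median_drift,
        "cp_model": gm.cp_model, "cp_robust": gm.cp_robust,
        "prop_unstable": gm.prop_unstable,
        "median_se_model": gm.median_se_model,
        "median_se_robust": gm.median_se_robust,
    }


def run_grid(
    scenarios: list[ScenarioConfig],
    methods: tuple[str, ...],
    n_sims: int,
    K: int,
    seed: int,
    output_path: str | Path,
    robust: bool = False,
    compute_drift: bool = False,
) -> pd.DataFrame:
    """Run many grid cells, checkpointing one CSV row per (scenario, method).

    An existing output file is treated as a checkpoint: completed
    (scenario, method) pairs are skipped and new rows appended, so an
    interrupted run resumed with the same arguments reproduces the
    uninterrupted table (per-scenario seeds derive from the scenario id, not
    the execution order).
    """
    output_path = Path(output_path)
    done: set[tuple[str, str]] = set()
    if output_path.exists():
        prev = pd.read_csv(output_path)
        done = set(zip(prev["scenario_id"], prev["method"]))
    output_path.parent.mkdir(parents=True, exist_ok=True)

    for i, cfg in enumerate(scenarios):
        sid = scenario_id(cfg)
        todo = tuple(m for m in methods if (sid, m) not in done)
        if not todo:
            continue
        sseed = _scenario_seed(seed, sid)
        log.info("scenario %d/%d %s (seed %d)", i + 1, len(scenarios), sid, sseed)
        res = run_scenario(cfg, todo, n_sims=n_sims, K=K, master_seed=sseed,
                           robust=robust, compute_drift=compute_drift)
        rows = pd.DataFrame(
            [_metrics_row(gm, sid, K, sseed) for gm in res.values()],
            columns=RESULTS_COLUMNS,
        )
        header = not output_path.exists()
        rows.to_csv(output_path, mode="a", header=header, index=False)
    return pd.read_csv(output_path)
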