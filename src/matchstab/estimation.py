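"""Odds-ratio estimation on matched or weighted samples with CR2 inference.

The outcome analysis is a logistic regression of the event indicator on the
treatment indicator over the analysis sample.  Because that model is
saturated in the two treatment arms, its MLE coincides with the 2x2-table
odds ratio and the model-based standard error with sqrt(1/a+1/b+1/c+1/d);
the closed form is used whenever all four cells are positive and the
iterative fit is retained for the sparse (separated) cases so their huge
standard errors feed the instability metrics instead of aborting the run.

Robust variances use the CR2 bias-reduced cluster sandwich (per-cluster
symmetric inverse-square-root adjustment of the working-model hat matrix)
with Satterthwaite degrees of freedom, applied to the IRLS working
representation of the logistic fit; matched sets act as clusters for matched
analyses and each subject is its own cluster for weighted analyses.

Weighting comparators: ATT weights (treated 1, control e/(1-e)), ATT with
subjects above the 95th percentile of the fitted propensity excluded, and
overlap weights (treated 1-e, control e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from ._glm import LogitFit, fit_logit
from .cohorts import Cohort
from .matching import MatchedSet

__all__ = [
    "EffectEstimate",
    "WeightScheme",
    "CR2Result",
    "UNSTABLE_SE_THRESHOLD",
    "cr2_vcov",
    "estimate_or_matched",
    "compute_weights",
    "estimate_or_weighted",
]

#: a model-based log-OR standard error above this marks the fit as unstable
UNSTABLE_SE_THRESHOLD = 100.0


@dataclass
class EffectEstimate:
    """Treatment odds ratio with model-based and cluster-robust inference."""

    or_hat: float
    log_or: float
    se_model: float                       # log-OR scale
    se_robust: float                      # log-OR scale; nan when not computed
    ci_model: tuple[float, float]
    ci_robust: tuple[float, float]
    df_robust: float
    converged: bool
    unstable: bool
    method: str = ""
    n_subjects: int = 0

    @property
    def stable(self) -> bool:
        return self.converged and np.isfinite(self.se_model) and not self.unstable


@dataclass
class WeightScheme:
    """Per-subject analysis weights for one weighting estimand."""

    kind: Literal["ATT", "ATT_trunc95", "ATO"]
    weights: np.ndarray


@dataclass
class CR2Result:
    vcov: np.ndarray
    satt_df: float
    fallback: bool = False      # True when CR1 scaling replaced the CR2 adjustment


def _mark_unstable(est: EffectEstimate) -> EffectEstimate:
    est.unstable = (not est.converged) or (not np.isfinite(est.se_model)) \
        or est.se_model > UNSTABLE_SE_THRESHOLD
    return est


def cr2_vcov(
    X: np.ndarray,
    fit: LogitFit,
    y: np.ndarray,
    clusters: np.ndarray,
    prior_weights: np.ndarray | None = None,
    coef_index: int = 1,
) -> CR2Result:
    """Bias-reduced (CR2) cluster-robust covariance with Satterthwaite df.

    Works on the weighted-least-squares representation of the logistic fit at
    convergence: with working weights W, let U = W^{1/2} X and transformed
    residuals  e~ = W^{-1/2} w0 (y - mu).  Each cluster's residuals are
    premultiplied by A_c = (I - U_c (U'U)^{-1} U_c')^{-1/2} (symmetric psd
    inverse square root), which makes the sandwich exactly unbiased under the
    working model; for singleton clusters this reduces to HC2.  The
    Satterthwaite degrees of freedom for the ``coef_index`` coefficient follow
    Bell–McCaffrey, treating the transformed errors as homoskedastic.

    Falls back to CR1-style scaling (with a warning and ``fallback=True``)
    when some (I - H_cc) is numerically singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    n, k = X.shape
    w0 = np.ones(n) if prior_weights is None else np.asarray(prior_weights, dtype=float)
    ids, inv = np.unique(clusters, return_inverse=True)
    n_c = len(ids)
    if n_c < 2:
        raise ValueError("CR2 requires at least two clusters")

    W = np.maximum(fit.working_weights, 1e-12)
    sw = np.sqrt(W)
    U = sw[:, None] * X
    M = np.linalg.inv(U.T @ U)
    resid_t = (w0 * (y - fit.fittedvalues)) / sw

    rows_by_cluster = [np.flatnonzero(inv == c) for c in range(n_c)]

    adj: list[np.ndarray] = []
    fallback = False
    for rows in rows_by_cluster:
        Uc = U[rows]
        Hcc = Uc @ M @ Uc.T
        eigval, eigvec = np.linalg.eigh(np.eye(len(rows)) - Hcc)
        if np.min(eigval) <= 1e-10:
            fallback = True
            break
        adj.append(eigvec @ np.diag(eigval ** -0.5) @ eigvec.T)

    if fallback:
        warnings.warn("CR2 adjustment singular for some cluster; using CR1 scaling")
        scale = np.sqrt(n_c / (n_c - 1.0) * max(n - 1.0, 1.0) / max(n - k, 1.0))
        adj = [scale * np.eye(len(rows)) for rows in rows_by_cluster]

    meat = np.zeros((k, k))
    g_list: list[np.ndarray] = []
    for rows, Ac in zip(rows_by_cluster, adj):
        gc = U[rows].T @ (Ac @ resid_t[rows])
        meat += np.outer(gc, gc)
    V = M @ meat @ M

    # Satterthwaite df for the requested coefficient: the variance estimator
    # is sum_c (q_c' e~_c)^2 with e~ = (I - H~) eps; collect the implied
    # linear forms g_c in the underlying errors and match two moments.
    ell = np.zeros(k)
    ell[coef_index] = 1.0
    B = U @ M                                   # n x k
    Htilde = U @ B.T                            # n x n working hat matrix
    ImH = np.eye(n) - Htilde
    G = np.empty((n, n_c))
    for c, (rows, Ac) in enumerate(zip(rows_by_cluster, adj)):
        qc = Ac @ (B[rows] @ ell)
        G[:, c] = ImH[rows].T @ qc
    S = G.T @ G
    tr = np.trace(S)
    denom = float(np.sum(S * S))
    satt_df = float(tr * tr / denom) if denom > 0 else float(n_c - 1)

    return CR2Result(vcov=V, satt_df=satt_df, fallback=fallback)


def _table_counts(y: np.ndarray, t: np.ndarray) -> tuple[float, float, float, float]:
    a = float(np.sum((t == 1) & (y == 1)))   # treated events
    b = float(np.sum((t == 1) & (y == 0)))
    c = float(np.sum((t == 0) & (y == 1)))   # control events
    d = float(np.sum((t == 0) & (y == 0)))
    return a, b, c, d


def _fit_outcome_logit(y: np.ndarray, t: np.ndarray,
                       prior_weights: np.ndarray | None = None) -> LogitFit:
    """Logistic fit of outcome on treatment; closed form when saturated cells allow."""
    if prior_weights is None:
        a, b, c, d = _table_counts(y, t)
        if min(a, b, c, d) > 0:
            log_or = np.log(a * d / (b * c))
            beta0 = np.log(c / d)
            mu = np.where(t == 1, a / (a + b), c / (c + d))
            cov = np.array([
                [1 / c + 1 / d, -(1 / c + 1 / d)],
                [-(1 / c + 1 / d), 1 / a + 1 / b + 1 / c + 1 / d],
            ])
            return LogitFit(
                params=np.array([beta0, log_or]),
                cov_params=cov,
                fittedvalues=mu,
                working_weights=mu * (1.0 - mu),
                converged=True,
                n_iter=0,
            )
    X = np.column_stack([np.ones(len(t)), t.astype(float)])
    return fit_logit(X, y.astype(float), prior_weights=prior_weights)


def _assemble_estimate(
    fit: LogitFit,
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray | None,
    prior_weights: np.ndarray | None,
    level: float,
    robust: bool,
    method: str,
) -> EffectEstimate:
    log_or = float(fit.params[1])
    se_model = float(fit.bse()[1])
    z = stats.norm.ppf(0.5 + level / 2.0)
    if np.isfinite(se_model):
        with np.errstate(over="ignore"):
            ci_model = (float(np.exp(log_or - z * se_model)),
                        float(np.exp(log_or + z * se_model)))
    else:
        ci_model = (0.0, np.inf)

    se_robust = np.nan
    ci_robust = (np.nan, np.nan)
    df_robust = np.nan
    if robust and clusters is not None:
        try:
            res = cr2_vcov(X, fit, y, clusters, prior_weights=prior_weights)
            se_robust = float(np.sqrt(max(res.vcov[1, 1], 0.0)))
            df_robust = res.satt_df
            tq = stats.t.ppf(0.5 + level / 2.0, df_robust) if df_robust > 0 else np.inf
            ci_robust = (float(np.exp(log_or - tq * se_robust)),
                         float(np.exp(log_or + tq * se_robust)))
        except (np.linalg.LinAlgError, ValueError):
            pass

    est = EffectEstimate(
        or_hat=float(np.exp(log_or)),
        log_or=log_or,
        se_model=se_model,
        se_robust=se_robust,
        ci_model=ci_model,
        ci_robust=ci_robust,
        df_robust=df_robust,
        converged=fit.converged,
        unstable=False,
        method=method,
        n_subjects=len(y),
    )
    return _mark_unstable(est)


def estimate_or_matched(
    cohort: Cohort,
    ms: MatchedSet,
    level: float = 0.95,
    robust: bool = True,
) -> EffectEstimate:
    """Odds ratio from the matched subjects, matched sets as clusters.

    For 1:1 matching the point estimate and model-based SE equal the 2x2
    table closed form; separated tables are fitted iteratively and flagged
    unstable rather than discarded.
    """
    if ms.n_matched_treated == 0:
        raise ValueError("matched set is empty")
    subj, clust = ms.matched_indices()
    y = np.asarray(cohort.outcome)[subj]
    t = np.asarray(cohort.treatment)[subj]
    fit = _fit_outcome_logit(y, t)
    X = np.column_stack([np.ones(len(t)), t.astype(float)])
    return _assemble_estimate(fit, X, y, clust, None, level, robust, "matched")


def compute_weights(e: np.ndarray, treatment: np.ndarray,
                    kind: Literal["ATT", "ATT_trunc95", "ATO"]) -> WeightScheme:
    """Propensity-based analysis weights.

    ATT: treated 1, control e/(1-e).  ATT_trunc95: ATT with every subject
    whose fitted propensity exceeds the 95th percentile of all fitted
    propensities excluded (weight 0).  ATO (overlap): treated 1-e, control e.
    """
    e = np.asarray(e, dtype=float)
    t = np.asarray(treatment)
    bad = np.flatnonzero((e <= 0.0) | (e >= 1.0))
    if bad.size:
        raise ValueError(f"degenerate propensity for subject(s) {bad[:5].tolist()}: weights undefined")
    if kind == "ATT":
        w = np.where(t == 1, 1.0, e / (1.0 - e))
    elif kind == "ATT_trunc95":
        w = np.where(t == 1, 1.0, e / (1.0 - e))
        cut = np.quantile(e, 0.95)      # type-7 linear interpolation
        w = np.where(e > cut, 0.0, w)
    elif kind == "ATO":
        w = np.where(t == 1, 1.0 - e, e)
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    return WeightScheme(kind=kind, weights=w)


def estimate_or_weighted(
    cohort: Cohort,
    ws: WeightScheme,
    level: float = 0.95,
    robust: bool = True,
) -> EffectEstimate:
    """Weighted logistic odds ratio; sandwich variance with singleton clusters."""
    y = np.asarray(cohort.outcome)
    t = np.asarray(cohort.treatment)
    w = ws.weights
    if w[t == 1].sum() <= 0 or w[t == 0].sum() <= 0:
        raise ValueError("positive total weight required in both arms")
    fit = _fit_outcome_logit(y, t, prior_weights=w)
    X = np.column_stack([np.ones(len(t)), t.astype(float)])
    clusters = np.arange(len(t))
    return _assemble_estimate(fit, X, y, clusters, w, level, robust, f"weighted:{ws.kind}")
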