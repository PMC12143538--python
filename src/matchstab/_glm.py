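"""Minimal logistic-regression IRLS that retains divergent fits.

Quantifying instability requires keeping separated / non-convergent fits
around with their (huge) standard errors instead of aborting: the proportion
of model-based log-OR standard errors above 100 is itself a study endpoint.
This fitter therefore never raises on separation — it runs Fisher scoring to
an iteration cap and reports the state it reached, mirroring how R's ``glm``
behaves on sparse matched samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

MAX_ITER = 100
TOL = 1e-8
_ETA_CLIP = 30.0      # expit saturates well before this; keeps weights > 0
_W_FLOOR = 1e-12


@dataclass
class LogitFit:
    """State of a (possibly non-convergent) logistic maximum-likelihood fit."""

    params: np.ndarray          # coefficients, intercept first
    cov_params: np.ndarray      # inverse Fisher information at the final iterate
    fittedvalues: np.ndarray    # probabilities mu_i
    working_weights: np.ndarray  # prior_w * mu * (1 - mu)
    converged: bool
    n_iter: int

    def bse(self) -> np.ndarray:
        d = np.diag(self.cov_params).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    prior_weights: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogitFit:
    """Fisher-scoring logistic fit of ``y`` (0/1) on design ``X``.

    ``prior_weights`` are nonnegative case weights entering both the score
    and the information.  Returns the final iterate whether or not the
    scoring converged; ``converged`` is False at the iteration cap or if the
    information matrix became numerically singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w0 = np.ones(n) if prior_weights is None else np.asarray(prior_weights, dtype=float)
    if np.any(w0 < 0):
        raise ValueError("prior weights must be nonnegative")

    beta = np.zeros(k)
    converged = False
    it = 0
    mu = np.full(n, 0.5)
    W = w0 * 0.25
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        W = w0 * mu * (1.0 - mu)
        Wf = np.maximum(W, _W_FLOOR)
        score = X.T @ (w0 * (y - mu))
        info = X.T @ (Wf[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    W = w0 * mu * (1.0 - mu)
    info = X.T @ (np.maximum(W, _W_FLOOR)[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.inf)
        converged = False
    return LogitFit(
        params=beta,
        cov_params=cov,
        fittedvalues=mu,
        working_weights=W,
        converged=converged,
        n_iter=it,
    )
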