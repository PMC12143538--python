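"""Greedy nearest-neighbor caliper matching on the logit propensity score.

Greedy matching walks through the treated subjects in some order and gives
each one its nearest not-yet-used control, provided the pair lies within the
caliper.  The result depends on that order, which is the instability this
package quantifies.  Four orders are implemented:

``HtoL`` / ``LtoH``
    treated processed by descending / ascending logit propensity;
``Clos``
    best-match-first: repeatedly pair the globally closest remaining
    (treated, control) pair;
``Rand``
    a uniformly random permutation of the treated subjects.

Matching is without replacement, on the logit scale, with the caliper set to
a fraction (default 25%) of the pooled sample SD of the logit propensity.

Tie-breaking is fully deterministic: equal logit scores during HtoL/LtoH
ordering break by ascending subject index; equidistant controls prefer the
lower logit score, then the lower index; Clos breaks global ties
lexicographically on (treated index, control index).
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._glm import LogitFit, fit_logit
from .cohorts import Cohort

__all__ = [
    "MatchSpec",
    "MatchedSet",
    "PropensityFit",
    "fit_propensity",
    "compute_caliper",
    "greedy_match",
    "brute_force_match_oracle",
]

_ORDERS = ("HtoL", "LtoH", "Clos", "Rand")


@dataclass(frozen=True)
class MatchSpec:
    """How one matching run is performed."""

    order: Literal["HtoL", "LtoH", "Clos", "Rand"] = "LtoH"
    ratio: int = 1
    caliper_fraction: float | None = 0.25
    rng_seed: int | None = None     # consumed only by order == "Rand"

    def __post_init__(self) -> None:
        if self.order not in _ORDERS:
            raise ValueError(f"unknown matching order {self.order!r}")
        if self.ratio not in (1, 2):
            raise ValueError("ratio must be 1 or 2")
        if self.caliper_fraction is not None and not self.caliper_fraction > 0:
            raise ValueError("caliper_fraction must be positive or None")


@dataclass
class MatchedSet:
    """Treated-to-controls pairing from one greedy matching run."""

    pairs: dict[int, list[int]]
    caliper_width: float            # logit scale; inf when matching uncalipered
    n_matched_treated: int
    n_unmatched_treated: int
    order_used: str
    spec: MatchSpec

    def matched_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Subject indices of the matched sample and their cluster (set) ids."""
        subj: list[int] = []
        clust: list[int] = []
        for t_idx in sorted(self.pairs):
            members = [t_idx] + self.pairs[t_idx]
            subj.extend(members)
            clust.extend([t_idx] * len(members))
        return np.asarray(subj, dtype=np.intp), np.asarray(clust, dtype=np.intp)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class PropensityFit:
    """Fitted logit propensity scores with the underlying MLE state."""

    logit_ps: np.ndarray
    params: np.ndarray
    converged: bool
    fit: LogitFit = field(repr=False)


def fit_propensity(cohort: Cohort | np.ndarray, treatment: np.ndarray | None = None) -> PropensityFit:
    """Logistic MLE of treatment on the covariate(s); returns fitted logit scores.

    Accepts either a :class:`~matchstab.cohorts.Cohort` (single covariate) or
    an explicit 2D covariate matrix plus a treatment vector (the user-table
    path, which may carry several columns).  Non-convergence or separation is
    flagged rather than raised — downstream consumers treat the dataset as
    unstable.
    """
    if isinstance(cohort, Cohort):
        x = cohort.covariate[:, None]
        t = np.asarray(cohort.treatment, dtype=float)
    else:
        x = np.asarray(cohort, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if treatment is None:
            raise ValueError("treatment vector required with an explicit covariate matrix")
        t = np.asarray(treatment, dtype=float)
    if t.sum() == 0 or t.sum() == len(t):
        raise ValueError("both treatment groups must be non-empty")
    X = np.column_stack([np.ones(len(t)), x])
    res = fit_logit(X, t)
    return PropensityFit(
        logit_ps=X @ res.params,
        params=res.params,
        converged=res.converged,
        fit=res,
    )


def compute_caliper(logit_ps: np.ndarray, fraction: float) -> float:
    """Caliper width: ``fraction`` times the pooled sample SD (ddof=1) of the logit scores."""
    logit_ps = np.asarray(logit_ps, dtype=float)
    if logit_ps.size < 2:
        raise ValueError("need at least two subjects to compute a caliper")
    sd = float(np.std(logit_ps, ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance in logit propensity scores: caliper is 0, no matches possible")
    return fraction * sd


class _ControlPool:
    """Sorted pool of available controls keyed by (logit score, index)."""

    def __init__(self, logits: np.ndarray, indices: np.ndarray) -> None:
        order = np.lexsort((indices, logits))
        self._logs: list[float] = [float(v) for v in logits[order]]
        self._idx: list[int] = [int(v) for v in indices[order]]

    def __len__(self) -> int:
        return len(self._logs)

    def nearest(self, target: float) -> tuple[int, float] | None:
        """Position and distance of the nearest control under the tie-break rules."""
        logs = self._logs
        n = len(logs)
        if n == 0:
            return None
        p = bisect_left(logs, target)
        d_right = logs[p] - target if p < n else np.inf
        d_left = target - logs[p - 1] if p > 0 else np.inf
        if d_left < d_right or (d_left == d_right and d_left < np.inf and d_left > 0):
            # equidistant -> lower logit wins, i.e. the left neighbour; among
            # equal-logit controls take the lowest index (leftmost duplicate)
            pos = p - 1
            while pos > 0 and logs[pos - 1] == logs[pos]:
                pos -= 1
            return pos, d_left
        if d_right < np.inf:
            return p, d_right       # exact hits land here; duplicates sorted by index
        return None

    def pop(self, pos: int) -> int:
        self._logs.pop(pos)
        return self._idx.pop(pos)


def _treated_order(t_indices: np.ndarray, t_logits: np.ndarray, order: str,
                   rng: np.random.Generator | None) -> np.ndarray:
    if order == "HtoL":
        return t_indices[np.argsort(-t_logits, kind="stable")]
    if order == "LtoH":
        return t_indices[np.argsort(t_logits, kind="stable")]
    if order == "Rand":
        if rng is None:
            raise ValueError("Rand order requires a seeded generator")
        return rng.permutation(t_indices)
    raise ValueError(order)


def _sequential_pass(sequence: np.ndarray, logit_ps: np.ndarray,
                     pool: _ControlPool, caliper: float) -> dict[int, int]:
    out: dict[int, int] = {}
    for ti in sequence:
        hit = pool.nearest(float(logit_ps[ti]))
        if hit is not None and hit[1] <= caliper:
            out[int(ti)] = pool.pop(hit[0])
    return out


def _closest_pass(t_indices: np.ndarray, logit_ps: np.ndarray,
                  pool: _ControlPool, caliper: float) -> dict[int, int]:
    """Best-match-first: globally minimal distance pair, lexicographic ties."""
    c_idx = np.asarray(pool._idx, dtype=np.intp)
    c_log = np.asarray(pool._logs, dtype=float)
    # re-sort columns by original control index so flat argmin is lexicographic
    col_order = np.argsort(c_idx, kind="stable")
    c_idx = c_idx[col_order]
    c_log = c_log[col_order]
    t_sorted = np.sort(t_indices)
    D = np.abs(logit_ps[t_sorted][:, None] - c_log[None, :])
    out: dict[int, int] = {}
    n_pairs = min(len(t_sorted), len(c_idx))
    for _ in range(n_pairs):
        flat = int(np.argmin(D))            # first minimum = lexicographic tie-break
        r, c = divmod(flat, D.shape[1])
        if not D[r, c] <= caliper:
            break
        out[int(t_sorted[r])] = int(c_idx[c])
        D[r, :] = np.inf
        D[:, c] = np.inf
    _remove_from_pool(pool, list(out.values()))
    return out


def _remove_from_pool(pool: _ControlPool, indices: list[int]) -> None:
    drop = set(indices)
    keep = [(lg, ix) for lg, ix in zip(pool._logs, pool._idx) if ix not in drop]
    pool._logs = [lg for lg, _ in keep]
    pool._idx = [ix for _, ix in keep]


def greedy_match(logit_ps: np.ndarray, treatment: np.ndarray, spec: MatchSpec) -> MatchedSet:
    """Greedy nearest-neighbor matching without replacement.

    1:2 matching runs two sequential passes in the same treated order: pass 1
    assigns every treated its first control (identical to the 1:1 result);
    pass 2 assigns second controls from the remaining pool.  Treated subjects
    with no control after pass 1 are dropped; those with a single control
    after pass 2 keep it (variable-ratio sets are retained).
    """
    logit_ps = np.asarray(logit_ps, dtype=float)
    treatment = np.asarray(treatment)
    t_indices = np.flatnonzero(treatment == 1)
    c_indices = np.flatnonzero(treatment == 0)
    if len(t_indices) == 0 or len(c_indices) == 0:
        raise ValueError("need at least one treated and one control subject")

    if spec.caliper_fraction is None:
        caliper = np.inf
    else:
        caliper = compute_caliper(logit_ps, spec.caliper_fraction)

    rng = None
    if spec.order == "Rand":
        seed = spec.rng_seed if spec.rng_seed is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E]))

    pool = _ControlPool(logit_ps[c_indices], c_indices)

    if spec.order == "Clos":
        first = _closest_pass(t_indices, logit_ps, pool, caliper)
    else:
        seq = _treated_order(t_indices, logit_ps[t_indices], spec.order, rng)
        first = _sequential_pass(seq, logit_ps, pool, caliper)

    pairs = {ti: [ci] for ti, ci in first.items()}
    if spec.ratio == 2 and first:
        eligible = np.asarray(sorted(first), dtype=np.intp)
        if spec.order == "Clos":
            second = _closest_pass(eligible, logit_ps, pool, caliper)
        else:
            seq2 = seq[np.isin(seq, eligible)]
            second = _sequential_pass(seq2, logit_ps, pool, caliper)
        for ti, ci in second.items():
            pairs[ti].append(ci)

    return MatchedSet(
        pairs=pairs,
        caliper_width=float(caliper),
        n_matched_treated=len(pairs),
        n_unmatched_treated=len(t_indices) - len(pairs),
        order_used=spec.order,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# test oracle

_ORACLE_MAX_N = 50


def brute_force_match_oracle(logit_ps: np.ndarray, treatment: np.ndarray,
                             spec: MatchSpec) -> MatchedSet:
    """Quadratic-scan reference implementation of the same matching contract.

    Independent of :func:`greedy_match`; guarded to tiny instances and meant
    for cross-checking only.
    """
    logit_ps = [float(v) for v in np.asarray(logit_ps, dtype=float)]
    treatment = [int(v) for v in np.asarray(treatment)]
    n = len(logit_ps)
    if n > _ORACLE_MAX_N:
        raise ValueError(f"oracle limited to N <= {_ORACLE_MAX_N}")
    treated = [i for i in range(n) if treatment[i] == 1]
    controls = [i for i in range(n) if treatment[i] == 0]
    if not treated or not controls:
        raise ValueError("need at least one treated and one control subject")

    if spec.caliper_fraction is None:
        cal = float("inf")
    else:
        m = sum(logit_ps) / n
        var = sum((v - m) ** 2 for v in logit_ps) / (n - 1)
        cal = spec.caliper_fraction * var ** 0.5

    if spec.order == "HtoL":
        full_order = sorted(treated, key=lambda i: (-logit_ps[i], i))
    elif spec.order == "LtoH":
        full_order = sorted(treated, key=lambda i: (logit_ps[i], i))
    elif spec.order == "Rand":
        seed = spec.rng_seed if spec.rng_seed is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E]))
        full_order = [int(v) for v in rng.permutation(np.asarray(treated, dtype=np.intp))]
    elif spec.order == "Clos":
        full_order = list(treated)
    else:  # pragma: no cover
        raise ValueError(spec.order)

    def pick_control(ti: int, avail: list[int]) -> int | None:
        best = None
        for ci in avail:
            d = abs(logit_ps[ti] - logit_ps[ci])
            if d > cal:
                continue
            key = (d, logit_ps[ci], ci)
            if best is None or key < best[0]:
                best = (key, ci)
        return None if best is None else best[1]

    def one_pass(tr: list[int], avail: list[int]) -> dict[int, int]:
        got: dict[int, int] = {}
        if spec.order == "Clos":
            remaining = sorted(tr)
            while remaining and avail:
                best = None
                for ti in remaining:
                    for ci in sorted(avail):
                        d = abs(logit_ps[ti] - logit_ps[ci])
                        key = (d, ti, ci)
                        if best is None or key < best:
                            best = key
                if best is None or best[0] > cal:
                    break
                _, ti, ci = best
                got[ti] = ci
                remaining.remove(ti)
                avail.remove(ci)
        else:
            # restrict the full-cohort processing order to this pass's treated
            for ti in [i for i in full_order if i in set(tr)]:
                ci = pick_control(ti, avail)
                if ci is not None:
                    got[ti] = ci
                    avail.remove(ci)
        return got

    avail = list(controls)
    first = one_pass(list(treated), avail)
    pairs = {ti: [ci] for ti, ci in first.items()}
    if spec.ratio == 2 and first:
        second = one_pass(sorted(first), avail)
        for ti, ci in second.items():
            pairs[ti].append(ci)

    return MatchedSet(
        pairs=pairs,
        caliper_width=float(cal),
        n_matched_treated=len(pairs),
        n_unmatched_treated=len(treated) - len(pairs),
        order_used=spec.order,
        spec=spec,
    )
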