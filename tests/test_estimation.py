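"""Odds-ratio estimation, CR2 robust variance, weighting comparators."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from matchstab._glm import fit_logit
from matchstab.cohorts import Cohort, ScenarioConfig, generate_cohort
from matchstab.estimation import (
    compute_weights,
    cr2_vcov,
    estimate_or_matched,
    estimate_or_weighted,
)
from matchstab.matching import MatchSpec, fit_propensity, greedy_match


def _pair_cohort(y_treated, y_control):
    """1:1 matched cohort: treated at even indices paired with odd ones."""
    k = len(y_treated)
    y = np.empty(2 * k, dtype=int)
    t = np.empty(2 * k, dtype=int)
    y[0::2], y[1::2] = y_treated, y_control
    t[0::2], t[1::2] = 1, 0
    coh = Cohort(covariate=np.zeros(2 * k), treatment=t, outcome=y,
                 true_propensity=np.full(2 * k, 0.5), seed_record=0)
    from matchstab.matching import MatchedSet
    ms = MatchedSet(pairs={2 * i: [2 * i + 1] for i in range(k)},
                    caliper_width=np.inf, n_matched_treated=k,
                    n_unmatched_treated=0, order_used="LtoH",
                    spec=MatchSpec("LtoH", caliper_fraction=None))
    return coh, ms


class TestMatchedEstimator:
    def test_two_by_two_closed_form(self):
        """Matched logistic OR/SE equals the 2x2-table closed form."""
        yt = np.r_[np.ones(5), np.zeros(15)].astype(int)
        yc = np.r_[np.ones(2), np.zeros(18)].astype(int)
        coh, ms = _pair_cohort(yt, yc)
        est = estimate_or_matched(coh, ms, robust=False)
        assert est.or_hat == pytest.approx(3.0, abs=1e-10)
        assert est.se_model == pytest.approx(
            np.sqrt(1 / 5 + 1 / 15 + 1 / 2 + 1 / 18), abs=1e-10)

    def test_closed_form_matches_iterative_mle(self):
        """Saturated two-group logistic: table estimate == IRLS to 1e-8."""
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 2, 30)
        yc = rng.integers(0, 2, 30)
        if yt.sum() in (0, 30):
            yt[0] = 1 - yt[0]
        if yc.sum() in (0, 30):
            yc[0] = 1 - yc[0]
        coh, ms = _pair_cohort(yt, yc)
        est = estimate_or_matched(coh, ms, robust=False)
        X = np.column_stack([np.ones(60), coh.treatment.astype(float)])
        it = fit_logit(X, coh.outcome.astype(float))
        assert est.log_or == pytest.approx(it.params[1], abs=1e-8)
        assert est.se_model == pytest.approx(it.bse()[1], abs=1e-8)

    def test_equal_rates_give_unit_or(self):
        yt = np.r_[np.ones(4), np.zeros(6)].astype(int)
        coh, ms = _pair_cohort(yt, yt.copy())
        est = estimate_or_matched(coh, ms, robust=False)
        assert est.or_hat == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_flags_unstable(self):
        yt = np.zeros(10, dtype=int)                    # no treated events
        yc = np.r_[np.ones(3), np.zeros(7)].astype(int)
        coh, ms = _pair_cohort(yt, yc)
        est = estimate_or_matched(coh, ms, robust=False)
        assert est.unstable
        assert est.se_model > 100 or not est.converged

    def test_logit_shift_invariance(self, small_cohort):
        """Adding a constant to every logit score changes no matched OR."""
        ps = fit_propensity(small_cohort)
        for order in ("HtoL", "LtoH", "Clos"):
            spec = MatchSpec(order, caliper_fraction=0.25)
            a = greedy_match(ps.logit_ps, small_cohort.treatment, spec)
            b = greedy_match(ps.logit_ps + 3.7, small_cohort.treatment, spec)
            assert a.pairs == b.pairs


def _cr2_oracle(X, mu, W, y, w0, cluster_ids):
    """Direct-formula CR2: independent dense implementation for tiny data."""
    X = np.asarray(X, float)
    n, k = X.shape
    sw = np.sqrt(W)
    U = sw[:, None] * X
    M = np.linalg.inv(U.T @ U)
    e = w0 * (y - mu) / sw
    meat = np.zeros((k, k))
    for cid in np.unique(cluster_ids):
        rows = np.flatnonzero(cluster_ids == cid)
        Uc = U[rows]
        I_H = np.eye(len(rows)) - Uc @ M @ Uc.T
        vals, vecs = np.linalg.eigh(I_H)
        A = vecs @ np.diag(vals ** -0.5) @ vecs.T
        g = Uc.T @ A @ e[rows]
        meat += np.outer(g, g)
    return M @ meat @ M


class TestCR2:
    def test_matrix_oracle_toy_pairs(self):
        """8 subjects in 4 pairs: CR2 equals the direct formula to 1e-10."""
        X = np.column_stack([np.ones(8), np.array([1, 0, 1, 0, 1, 0, 1, 0], float)])
        y = np.array([1, 0, 0, 0, 1, 1, 0, 1], float)
        clusters = np.repeat(np.arange(4), 2)
        fit = fit_logit(X, y)
        res = cr2_vcov(X, fit, y, clusters)
        V = _cr2_oracle(X, fit.fittedvalues, np.maximum(fit.working_weights, 1e-12),
                        y, np.ones(8), clusters)
        np.testing.assert_allclose(res.vcov, V, atol=1e-10)

    def test_singleton_clusters_reduce_to_hc2(self):
        """With one subject per cluster CR2 is the HC2 sandwich (R convention)."""
        rng = np.random.default_rng(3)
        n = 60
        t = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(0.3 * t - 0.2)).astype(float)
        X = np.column_stack([np.ones(n), t])
        fit = fit_logit(X, y)
        res = cr2_vcov(X, fit, y, np.arange(n))
        # HC2 on the GLM working representation: x x' (y-mu)^2 / (1 - h~)
        W = np.maximum(fit.working_weights, 1e-12)
        U = np.sqrt(W)[:, None] * X
        M = np.linalg.inv(U.T @ U)
        h = np.einsum("ij,jk,ik->i", U, M, U)
        r2 = (y - fit.fittedvalues) ** 2 / (1 - h)
        hc2 = M @ (X.T @ (r2[:, None] * X)) @ M
        np.testing.assert_allclose(res.vcov, hc2, atol=1e-12)

    def test_symmetric_positive_semidefinite(self, small_cohort):
        ps = fit_propensity(small_cohort)
        ms = greedy_match(ps.logit_ps, small_cohort.treatment, MatchSpec("Clos"))
        subj, clust = ms.matched_indices()
        y = small_cohort.outcome[subj].astype(float)
        X = np.column_stack([np.ones(len(subj)),
                             small_cohort.treatment[subj].astype(float)])
        fit = fit_logit(X, y)
        res = cr2_vcov(X, fit, y, clust)
        np.testing.assert_allclose(res.vcov, res.vcov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(res.vcov) > -1e-12)
        assert res.satt_df > 0

    def test_requires_two_clusters(self):
        X = np.column_stack([np.ones(4), np.array([1., 0, 1, 0])])
        y = np.array([1., 0, 0, 1])
        fit = fit_logit(X, y)
        with pytest.raises(ValueError, match="two clusters"):
            cr2_vcov(X, fit, y, np.zeros(4))


class TestWeights:
    def test_att_weight_values(self):
        e = np.array([0.8, 0.8])
        t = np.array([0, 1])
        ws = compute_weights(e, t, "ATT")
        np.testing.assert_allclose(ws.weights, [4.0, 1.0])

    def test_ato_weights_at_half(self):
        ws = compute_weights(np.array([0.5, 0.5]), np.array([0, 1]), "ATO")
        np.testing.assert_allclose(ws.weights, [0.5, 0.5])

    def test_truncation_zeroes_top_five_percent(self):
        rng = np.random.default_rng(9)
        e = rng.uniform(0.05, 0.95, 100)
        t = rng.integers(0, 2, 100)
        ws = compute_weights(e, t, "ATT_trunc95")
        dropped = np.flatnonzero(ws.weights == 0.0)
        # type-7 95th percentile of 100 distinct values leaves exactly the top 5 above it
        assert set(dropped) == set(np.argsort(e)[-5:])

    def test_degenerate_propensity_named(self):
        with pytest.raises(ValueError, match="subject"):
            compute_weights(np.array([0.5, 1.0]), np.array([0, 1]), "ATT")


class TestWeightedEstimator:
    def test_unit_weights_equal_full_cohort_logistic(self, small_cohort):
        from matchstab.estimation import WeightScheme
        ws = WeightScheme(kind="ATT", weights=np.ones(small_cohort.n))
        est = estimate_or_weighted(small_cohort, ws, robust=False)
        X = sm.add_constant(small_cohort.treatment.astype(float))
        ref = sm.GLM(small_cohort.outcome.astype(float), X,
                     family=sm.families.Binomial()).fit()
        assert est.log_or == pytest.approx(ref.params[1], abs=1e-7)
        assert est.se_model == pytest.approx(ref.bse[1], abs=1e-7)

    def test_overlap_weights_balance_covariate_exactly(self, small_cohort):
        """Fitted-logistic overlap weights equalize covariate means across arms."""
        ps = fit_propensity(small_cohort)
        e = expit(ps.logit_ps)
        ws = compute_weights(e, small_cohort.treatment, "ATO")
        t = small_cohort.treatment.astype(bool)
        x = small_cohort.covariate
        m1 = np.average(x[t], weights=ws.weights[t])
        m0 = np.average(x[~t], weights=ws.weights[~t])
        assert m1 == pytest.approx(m0, abs=1e-6)

    def test_positive_weight_required_in_both_arms(self, small_cohort):
        from matchstab.estimation import WeightScheme
        w = np.where(small_cohort.treatment == 1, 0.0, 1.0)
        with pytest.raises(ValueError, match="both arms"):
            estimate_or_weighted(small_cohort, WeightScheme(kind="ATT", weights=w))


class TestNullRecovery:
    def test_median_or_near_one_for_clos_and_ato(self):
        """At true OR 1 and weak confounding the estimators center on 1."""
        from matchstab.simulation import run_scenario
        cfg = ScenarioConfig(pg=0.2, c_target=0.6, pe=0.3, true_or=1.0, n=400)
        res = run_scenario(cfg, methods=("M_Clos", "W_ATO"), n_sims=500,
                           K=1, master_seed=31)
        assert 0.93 < res["M_Clos"].median_or < 1.08
        assert 0.93 < res["W_ATO"].median_or < 1.08
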