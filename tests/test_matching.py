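"""Greedy caliper matching: orders, tie-breaks, invariants, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matchstab.cohorts import Cohort, ScenarioConfig, generate_cohort
from matchstab.io import read_matched_set, write_matched_set
from matchstab.matching import (
    MatchSpec,
    brute_force_match_oracle,
    compute_caliper,
    fit_propensity,
    greedy_match,
)

from conftest import rand_instance


def _frac_for(logits, caliper):
    """Caliper fraction that yields the requested absolute width on this data."""
    sd = np.std(np.asarray(logits, float), ddof=1)
    return caliper / sd


class TestFitPropensity:
    def test_perfectly_balanced_gives_zero_coefficients(self):
        coh = Cohort(covariate=np.array([1.0, -1.0, 1.0, -1.0]),
                     treatment=np.array([1, 1, 0, 0]),
                     outcome=np.zeros(4, dtype=int),
                     true_propensity=np.full(4, 0.5), seed_record=0)
        ps = fit_propensity(coh)
        np.testing.assert_allclose(ps.params, [0.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(ps.logit_ps, 0.0, atol=1e-8)

    def test_mean_fitted_probability_equals_treated_fraction(self, small_cohort):
        from scipy.special import expit
        ps = fit_propensity(small_cohort)
        assert expit(ps.logit_ps).mean() == pytest.approx(
            small_cohort.treatment.mean(), abs=1e-8)

    def test_mle_recovers_generating_coefficients(self):
        from matchstab.cohorts import calibrate_propensity, CovariateSpec
        pm = calibrate_propensity(CovariateSpec("unimodal"), 0.2, 0.85)
        cfg = ScenarioConfig(pg=0.2, c_target=0.85, n=100_000)
        coh = generate_cohort(cfg, 18)
        ps = fit_propensity(coh)
        # asymptotic SEs from the information matrix
        se = ps.fit.bse()
        assert abs(ps.params[0] - pm.intercept) < 3 * se[0]
        assert abs(ps.params[1] - pm.slope) < 3 * se[1]

    def test_one_armed_cohort_rejected(self):
        coh = Cohort(covariate=np.zeros(3), treatment=np.ones(3, dtype=int),
                     outcome=np.zeros(3, dtype=int),
                     true_propensity=np.full(3, 0.5), seed_record=0)
        with pytest.raises(ValueError, match="non-empty"):
            fit_propensity(coh)


class TestComputeCaliper:
    def test_hand_arithmetic(self):
        assert compute_caliper(np.array([0.0, 2.0]), 0.25) == pytest.approx(
            0.25 * np.sqrt(2.0))

    def test_zero_fraction(self):
        assert compute_caliper(np.array([0.0, 1.0, 2.0]), 0.0) == 0.0

    def test_constant_logits_warn_and_block_matching(self):
        lp = np.zeros(6)
        with pytest.warns(UserWarning, match="zero variance"):
            assert compute_caliper(lp, 0.25) == 0.0
        # caliper 0 with exactly-tied scores still matches at distance 0
        ms = greedy_match(lp, np.array([1, 0, 1, 0, 1, 0]),
                          MatchSpec("LtoH", caliper_fraction=None))
        assert ms.n_matched_treated == 3


class TestGreedyOrders:
    def test_hand_traced_orders(self):
        # treated logits .50 and .47 compete for the single control at .49
        lp = np.array([0.50, 0.47, 0.49])
        t = np.array([1, 1, 0])
        frac = _frac_for(lp, 0.10)
        assert greedy_match(lp, t, MatchSpec("HtoL", caliper_fraction=frac)).pairs == {0: [2]}
        assert greedy_match(lp, t, MatchSpec("LtoH", caliper_fraction=frac)).pairs == {1: [2]}
        # best-match-first resolves the competition by distance: .01 < .02
        assert greedy_match(lp, t, MatchSpec("Clos", caliper_fraction=frac)).pairs == {0: [2]}

    def test_caliper_excludes_distant_pair(self):
        lp = np.array([0.9, 0.2])
        t = np.array([1, 0])
        frac = _frac_for(lp, 0.5)
        ms = greedy_match(lp, t, MatchSpec("HtoL", caliper_fraction=frac))
        assert ms.pairs == {} and ms.n_unmatched_treated == 1

    def test_competition_free_orders_agree(self):
        # each treated's private nearest control: far-apart (t, c) blocks
        lp = np.array([0.0, 0.05, 2.0, 2.04, 4.0, 4.03])
        t = np.array([1, 0, 1, 0, 1, 0])
        frac = _frac_for(lp, 0.2)
        results = []
        for order in ("HtoL", "LtoH", "Clos", "Rand"):
            for seed in (1, 2):
                ms = greedy_match(lp, t, MatchSpec(order, caliper_fraction=frac, rng_seed=seed))
                results.append(ms.pairs)
        assert all(r == {0: [1], 2: [3], 4: [5]} for r in results)

    def test_rand_reproducible(self):
        rng = np.random.default_rng(3)
        lp, t = rand_instance(rng)
        spec = MatchSpec("Rand", caliper_fraction=0.5, rng_seed=42)
        assert greedy_match(lp, t, spec).pairs == greedy_match(lp, t, spec).pairs

    def test_ratio2_first_pass_equals_1to1(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            lp, t = rand_instance(rng)
            one = greedy_match(lp, t, MatchSpec("LtoH", ratio=1, caliper_fraction=0.5))
            two = greedy_match(lp, t, MatchSpec("LtoH", ratio=2, caliper_fraction=0.5))
            assert {k: v[0] for k, v in two.pairs.items()} == {
                k: v[0] for k, v in one.pairs.items()}


class TestInvariants:
    @pytest.mark.parametrize("order", ["HtoL", "LtoH", "Clos", "Rand"])
    @pytest.mark.parametrize("ratio", [1, 2])
    def test_without_replacement_and_caliper_respect(self, order, ratio):
        rng = np.random.default_rng(order.encode()[0] + ratio)
        for trial in range(40):
            lp, t = rand_instance(rng, tied=(trial % 2 == 0))
            spec = MatchSpec(order, ratio=ratio, caliper_fraction=0.4, rng_seed=trial)
            ms = greedy_match(lp, t, spec)
            used = [c for v in ms.pairs.values() for c in v]
            assert len(used) == len(set(used))
            for ti, cs in ms.pairs.items():
                assert t[ti] == 1
                assert len(cs) <= ratio
                for ci in cs:
                    assert t[ci] == 0
                    assert abs(lp[ti] - lp[ci]) <= ms.caliper_width

    def test_permutation_equivariance(self):
        """Relabeling subjects permutes the matched set identically (no ties)."""
        rng = np.random.default_rng(55)
        lp, t = rand_instance(rng, tied=False)
        perm = rng.permutation(len(lp))
        inv = np.argsort(perm)
        for order in ("HtoL", "LtoH", "Clos"):
            a = greedy_match(lp, t, MatchSpec(order, caliper_fraction=0.4))
            b = greedy_match(lp[perm], t[perm], MatchSpec(order, caliper_fraction=0.4))
            relabeled = {int(inv[ti]): [int(inv[ci]) for ci in cs]
                         for ti, cs in a.pairs.items()}
            assert b.pairs == relabeled

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           order=st.sampled_from(["HtoL", "LtoH", "Clos", "Rand"]),
           ratio=st.sampled_from([1, 2]))
    def test_oracle_parity_property(self, seed, order, ratio):
        rng = np.random.default_rng(seed)
        lp, t = rand_instance(rng, tied=(seed % 3 == 0))
        spec = MatchSpec(order, ratio=ratio, caliper_fraction=0.35, rng_seed=seed)
        assert greedy_match(lp, t, spec).pairs == \
            brute_force_match_oracle(lp, t, spec).pairs


class TestOracle:
    def test_size_guard(self):
        lp = np.zeros(60)
        t = np.r_[np.ones(30), np.zeros(30)].astype(int)
        with pytest.raises(ValueError, match="oracle"):
            brute_force_match_oracle(lp, t, MatchSpec("LtoH"))

    def test_single_pair_within_caliper(self):
        lp = np.array([0.1, 0.15])
        t = np.array([1, 0])
        ms = brute_force_match_oracle(lp, t, MatchSpec("LtoH", caliper_fraction=None))
        assert ms.pairs == {0: [1]}


def test_matched_set_csv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    lp, t = rand_instance(rng)
    ms = greedy_match(lp, t, MatchSpec("LtoH", ratio=2, caliper_fraction=0.5))
    path = tmp_path / "pairs.csv"
    write_matched_set(ms, lp, path)
    assert read_matched_set(path) == ms.pairs
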