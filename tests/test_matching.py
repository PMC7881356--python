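"""Panel-matching estimator: set construction, refinement, DiD, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import policymatch as pm
from policymatch import matching, reference
from policymatch.matching import (_att_profile_array, _first_adoption,
                                  _sets_array, _uniform, bootstrap_ci,
                                  entropy_weights, find_matched_sets,
                                  refine_weights)


def wide(arr, states=None):
    arr = np.asarray(arr)
    states = states or [chr(65 + i) for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=states)


def staggered_panel(rng, n_states=10, n_quarters=20, hazard=0.08):
    T = np.zeros((n_states, n_quarters), dtype=np.int8)
    for s in range(n_states):
        hit = np.flatnonzero(rng.random(n_quarters) < hazard)
        if len(hit):
            T[s, hit[0]:] = 1
    return T


class TestMatchedSets:
    def test_single_adopter_matched_to_never_treated(self):
        T = np.zeros((3, 12), dtype=np.int8)
        T[0, 5:] = 1
        sets = find_matched_sets(wide(T), L=4)
        assert len(sets) == 1
        m = sets[0]
        assert (m.treated_state, m.t, m.controls) == ("A", 5, ["B", "C"])
        assert np.allclose(m.weights, [0.5, 0.5])

    def test_simultaneous_adoption_leaves_no_controls(self):
        T = np.zeros((4, 12), dtype=np.int8)
        T[:, 5:] = 1
        sets = find_matched_sets(wide(T), L=4)
        assert len(sets) == 4 and all(m.empty for m in sets)

    def test_insufficient_pre_period_skipped(self):
        T = np.zeros((3, 12), dtype=np.int8)
        T[0, 2:] = 1  # adopts at t=2 < L=4
        assert find_matched_sets(wide(T), L=4) == []

    def test_non_absorbing_panel_rejected(self):
        T = np.zeros((2, 8), dtype=np.int8)
        T[0, 2:5] = 1  # switches back off
        with pytest.raises(ValueError, match="absorbing"):
            find_matched_sets(wide(T), L=2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = staggered_panel(rng)
        fast = [(s, t, sorted(c)) for s, t, c in _sets_array(T, 4)]
        brute = [(s, t, sorted(c)) for s, t, c in reference.brute_matched_sets(T, 4)
                 ]
        # fast path keeps empty-control sets too; brute enumerates identically
        assert fast == brute


class TestATT:
    def test_two_period_reduction_equals_classical_did(self):
        # treated change +5, control change +2 → ATT 3
        T = np.zeros((2, 4), dtype=np.int8)
        T[0, 2:] = 1
        Y = np.array([[1.0, 1.0, 6.0, 6.0], [2.0, 2.0, 4.0, 4.0]])
        sets = _uniform(_sets_array(T, 1))
        est, _ = _att_profile_array(sets, Y, 0, adopt=_first_adoption(T))
        expected = reference.classical_did_2x2(1.0, 6.0, 2.0, 4.0)
        assert est[0] == pytest.approx(expected) == 3.0

    def test_noise_free_injected_effect_recovered_exactly(self):
        sched = [-0.5] * 13
        cfg = pm.SimConfig(n_states=8, n_quarters=20, adoption_hazard=0.06,
                           noise_sd=0.0, pre_trend_slope_sd=0.0,
                           true_effect_schedule={"pdmp_mandatory": {"outcome": sched}},
                           seed=5)
        pol = pm.simulate_policy_adoption(cfg)
        out = pm.simulate_state_outcomes(cfg, pol)
        panel = pm.build_treatment_panel(pol, cfg.window)
        from policymatch.policies import treatment_matrix
        wt, T = treatment_matrix(panel, "pdmp_mandatory")
        wy = out.pivot(index="state", columns="quarter", values="outcome").reindex(wt.index)
        sets = _uniform(_sets_array(T, 4))
        est, n = _att_profile_array(sets, wy.to_numpy(float), 12,
                                    adopt=_first_adoption(T))
        assert (n > 0).any()
        assert np.allclose(est[n > 0], -0.5)

    def test_zero_effect_zero_noise_gives_exact_zero_everywhere(self):
        cfg = pm.SimConfig(n_states=6, n_quarters=16, adoption_hazard=0.08,
                           noise_sd=0.0, pre_trend_slope_sd=0.0, seed=2)
        pol = pm.simulate_policy_adoption(cfg)
        out = pm.simulate_state_outcomes(cfg, pol)
        panel = pm.build_treatment_panel(pol, cfg.window)
        from policymatch.policies import treatment_matrix
        wt, T = treatment_matrix(panel, "naloxone_access")
        wy = out.pivot(index="state", columns="quarter", values="outcome").reindex(wt.index)
        ests = bootstrap_ci(wt, wy, L=2, f_max=6, B=100, seed=0)
        for e in ests:
            if np.isfinite(e.estimate):
                assert e.estimate == pytest.approx(0.0, abs=1e-12)
                assert (e.ci_low, e.ci_high) == (pytest.approx(0, abs=1e-12),) * 2

    @pytest.mark.parametrize("seed", range(4))
    def test_att_matches_bruteforce_on_small_panels(self, seed):
        rng = np.random.default_rng(40 + seed)
        T = staggered_panel(rng, n_states=6, n_quarters=12, hazard=0.12)
        Y = rng.normal(0, 1, T.shape)
        sets = _uniform(_sets_array(T, 2))
        est, _ = _att_profile_array(sets, Y, 6, adopt=_first_adoption(T))
        for F in range(7):
            brute = reference.brute_att(
                [(s, t, list(c), list(w)) for s, t, c, w in sets], Y, T, F)
            if np.isnan(brute):
                assert np.isnan(est[F])
            else:
                assert est[F] == pytest.approx(brute, rel=1e-12)

    def test_state_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        T = staggered_panel(rng, 8, 16, 0.1)
        Y = rng.normal(0, 1, T.shape)
        states = [f"S{i}" for i in range(8)]
        wt, wy = wide(T, states), wide(Y, states)
        base = bootstrap_ci(wt, wy, L=2, f_max=4, B=100, seed=11)
        perm = rng.permutation(8)
        base_p = bootstrap_ci(wt.iloc[perm], wy.iloc[perm], L=2, f_max=4, B=100, seed=11)
        for a, b in zip(base, base_p):
            assert a.estimate == pytest.approx(b.estimate, nan_ok=True)
            assert a.ci_low == pytest.approx(b.ci_low, nan_ok=True)

    def test_bootstrap_seeded_determinism(self):
        rng = np.random.default_rng(8)
        T = staggered_panel(rng, 10, 20, 0.08)
        Y = rng.normal(0, 1, T.shape)
        a = bootstrap_ci(wide(T), wide(Y), L=2, f_max=6, B=150, seed=99)
        b = bootstrap_ci(wide(T), wide(Y), L=2, f_max=6, B=150, seed=99)
        assert all(x == y for x, y in zip(a, b))


class TestRefinement:
    def _setup(self, n_states=6, n_quarters=16, seed=0):
        rng = np.random.default_rng(seed)
        T = np.zeros((n_states, n_quarters), dtype=np.int8)
        T[0, 8:] = 1
        Y = rng.normal(0, 1, (n_states, n_quarters))
        cov = pd.DataFrame(
            [(chr(65 + s), q, rng.normal(), rng.normal())
             for s in range(n_states) for q in range(n_quarters)],
            columns=["state", "quarter", "x1", "x2"],
        )
        return wide(T), wide(Y), cov

    @pytest.mark.parametrize("method", ["cbps", "entropy", "ipw", "nn", "uniform"])
    def test_single_control_forced_to_weight_one(self, method):
        T = np.zeros((2, 12), dtype=np.int8)
        T[0, 6:] = 1
        rng = np.random.default_rng(0)
        Y = wide(rng.normal(0, 1, (2, 12)))
        sets = find_matched_sets(wide(T), L=2)
        refined = refine_weights(sets, Y, method=method, L=2)
        assert np.allclose(refined[0].weights, [1.0])

    def test_identical_controls_share_weight_equally(self):
        T = np.zeros((3, 12), dtype=np.int8)
        T[0, 6:] = 1
        Y = np.vstack([np.linspace(0, 1, 12),
                       np.linspace(1, 2, 12),
                       np.linspace(1, 2, 12)])  # controls identical
        sets = find_matched_sets(wide(T), L=2)
        for method in ("entropy", "nn", "ipw"):
            refined = refine_weights(sets, wide(Y), method=method, L=2, j=2)
            assert np.allclose(refined[0].weights, [0.5, 0.5]), method

    def test_entropy_weights_achieve_exact_balance(self):
        # treated inside the control hull: an exact-balance solution exists
        x_t = np.array([0.2, -0.1])
        Xc = np.array([[1.0, 0.0], [-1.0, 0.5], [0.5, -1.5]])
        w = entropy_weights(x_t, Xc)
        assert w.sum() == pytest.approx(1.0)
        assert np.max(np.abs(w @ Xc - x_t)) < 1e-6

    def test_entropy_infeasible_raises(self):
        x_t = np.array([10.0, 10.0])  # far outside the hull
        Xc = np.array([[1.0, 0.0], [-1.0, 0.5], [0.5, -1.5]])
        with pytest.raises(ValueError, match="exact-balance"):
            entropy_weights(x_t, Xc)

    def test_cbps_balances_pooled_moments(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (400, 3))
        beta_true = np.array([0.2, 0.8, -0.5, 0.3])
        p = 1 / (1 + np.exp(-(np.c_[np.ones(400), X] @ beta_true)))
        treated = rng.random(400) < p
        e = matching.cbps_propensity(X, treated)
        odds = e[~treated] / (1 - e[~treated])
        bal_c = odds @ X[~treated] / odds.sum()
        assert np.max(np.abs(bal_c - X[treated].mean(axis=0))) < 1e-6

    def test_refined_weights_sum_to_one_and_nonnegative(self):
        wt, wy, cov = self._setup()
        sets = find_matched_sets(wt, L=4)
        for method in ("cbps", "entropy", "ipw", "nn"):
            refined = refine_weights(sets, wy, covariates=cov, L=4, method=method)
            for m in refined:
                if not m.empty:
                    assert m.weights.min() >= 0
                    assert m.weights.sum() == pytest.approx(1.0)

    def test_nn_tie_break_is_lexicographic(self):
        w = matching.mahalanobis_nn_weights(
            np.array([0.0, 0.0]),
            np.array([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0]]),
            ["B", "A", "C"], j=1,
        )
        assert np.allclose(w, [0.0, 1.0, 0.0])  # tie between A and B → A wins
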