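"""Synthetic-data generator: adoption process, outcome DGP, claim streams."""

import numpy as np
import pandas as pd
import pytest

import policymatch as pm
from policymatch.policies import treatment_matrix
from policymatch.simulate import SimConfig, schedule_value


def small_cfg(**kw):
    base = dict(n_states=6, n_quarters=12, patients_per_state=20,
                adoption_hazard=0.05, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_quarters=1),
        dict(adoption_hazard=1.5),
        dict(adoption_hazard=-0.1),
        dict(noise_sd=-1),
        dict(true_effect_schedule={"pdmp_access": {"outcome": []}}),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_schedule_plateaus_beyond_last_lead(self):
        assert schedule_value([0.0, -0.5, -1.0], 10) == -1.0
        assert schedule_value([0.0, -0.5, -1.0], -3) == 0.0


class TestAdoption:
    def test_zero_hazard_nobody_adopts(self):
        pol = pm.simulate_policy_adoption(small_cfg(adoption_hazard=0.0))
        assert pol["effective_year"].isna().all()

    def test_certain_hazard_everyone_adopts_first_quarter(self):
        cfg = small_cfg(adoption_hazard=1.0)
        pol = pm.simulate_policy_adoption(cfg)
        assert (pol["effective_year"] == cfg.start_year).all()
        assert pol["effective_month"].between(1, 3).all()

    def test_seeded_determinism(self):
        cfg = small_cfg(seed=7)
        a = pm.simulate_policy_adoption(cfg)
        b = pm.simulate_policy_adoption(small_cfg(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_adoption_time_decreases_with_hazard(self):
        """Stochastic monotonicity over 200 replicates."""
        means = []
        for hazard in (0.02, 0.10):
            qs = []
            for r in range(200):
                cfg = SimConfig(n_states=5, n_quarters=24, patients_per_state=0,
                                adoption_hazard=hazard, seed=3000 + r)
                pol = pm.simulate_policy_adoption(cfg)
                adopted = pol.dropna(subset=["effective_year"])
                qs.extend(
                    cfg.window.quarter_of_month(y, m)
                    for y, m in zip(adopted["effective_year"],
                                    adopted["effective_month"])
                )
            means.append(np.mean(qs))
        assert means[1] < means[0]


class TestOutcomes:
    def test_null_model_trajectories_parallel_up_to_intercepts(self):
        cfg = small_cfg(noise_sd=0.0, pre_trend_slope_sd=0.0, adoption_hazard=0.2)
        pol = pm.simulate_policy_adoption(cfg)
        out = pm.simulate_state_outcomes(cfg, pol)
        wideo = out.pivot(index="state", columns="quarter", values="outcome")
        demeaned = wideo.sub(wideo.mean(axis=1), axis=0)
        assert np.allclose(demeaned.to_numpy() - demeaned.to_numpy()[0], 0.0)

    def test_injected_step_appears_at_adoption(self):
        sched = [-0.5] * 13
        cfg = small_cfg(noise_sd=0.0, pre_trend_slope_sd=0.0, adoption_hazard=0.3,
                        true_effect_schedule={"pain_clinic": {"outcome": sched}})
        pol = pm.simulate_policy_adoption(cfg)
        out = pm.simulate_state_outcomes(cfg, pol)
        null = pm.simulate_state_outcomes(
            small_cfg(noise_sd=0.0, pre_trend_slope_sd=0.0, adoption_hazard=0.3), pol)
        panel = pm.build_treatment_panel(pol, cfg.window)
        _, T = treatment_matrix(panel, "pain_clinic")
        diff = (out["outcome"] - null["outcome"]).to_numpy().reshape(T.shape)
        assert np.allclose(diff[T == 1], -0.5)
        assert np.allclose(diff[T == 0], 0.0)

    def test_seeded_panel_bit_reproducible(self):
        cfg = small_cfg(seed=11, noise_sd=1.0)
        pol = pm.simulate_policy_adoption(cfg)
        a = pm.simulate_state_outcomes(cfg, pol)
        b = pm.simulate_state_outcomes(small_cfg(seed=11, noise_sd=1.0), pol)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_state_in_policy_table_rejected(self):
        cfg = small_cfg()
        pol = pm.simulate_policy_adoption(cfg)
        pol.loc[0, "state"] = "ZZ"
        with pytest.raises(ValueError, match="unknown states"):
            pm.simulate_state_outcomes(cfg, pol)


class TestClaims:
    def test_empty_cohort_yields_empty_claims(self):
        cfg = small_cfg(patients_per_state=0)
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        assert len(bundle.claims) == 0 and len(bundle.roster) == 0

    def test_rng_streams_independent_across_components(self):
        """Changing claim parameters must not perturb outcome draws."""
        cfg1 = small_cfg(seed=5)
        cfg2 = small_cfg(seed=5, patients_per_state=50, shopper_rate=0.1)
        pol = pm.simulate_policy_adoption(cfg1)
        pd.testing.assert_frame_equal(pm.simulate_policy_adoption(cfg2), pol)
        pd.testing.assert_frame_equal(
            pm.simulate_state_outcomes(cfg1, pol),
            pm.simulate_state_outcomes(cfg2, pol),
        )

    def test_bundle_determinism(self):
        cfg = small_cfg(seed=9)
        pol = pm.simulate_policy_adoption(cfg)
        a = pm.simulate_claims(cfg, pol)
        b = pm.simulate_claims(small_cfg(seed=9), pol)
        pd.testing.assert_frame_equal(a.claims, b.claims)
        pd.testing.assert_frame_equal(a.deaths, b.deaths)

    def test_diagnosis_universe_within_roster(self):
        cfg = small_cfg(patients_per_state=40, cancer_rate=0.1)
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        assert set(bundle.diagnoses["patient_id"]) <= set(bundle.roster["patient_id"])

    def test_planted_shopper_flagged_downstream(self):
        cfg = small_cfg(patients_per_state=30, shopper_rate=0.5, seed=21)
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        table = pm.compute_indicators(bundle.claims, bundle.diagnoses,
                                      bundle.roster, cfg.window)
        assert (table["p_doctor_shopping"].fillna(0) > 0).any()

    def test_indicator_recovery_matches_generator_target(self):
        """State-quarter any-opioid proportion tracks the stored target
        within binomial error at 2000 patients per state."""
        cfg = SimConfig(n_states=3, n_quarters=8, patients_per_state=2000,
                        adoption_hazard=0.1, seed=13,
                        claim_effect_schedule={"pdmp_mandatory": [-0.04] * 4})
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        table = pm.compute_indicators(bundle.claims, bundle.diagnoses,
                                      bundle.roster, cfg.window)
        merged = table.merge(bundle.truth["targets"], on=["state", "quarter"])
        p = merged["target_p_any_opioid"]
        n = merged["n_enrollees"]
        z = (merged["p_any_opioid"] - p) / np.sqrt(p * (1 - p) / n)
        # 24 state-quarters; allow 4 sigma with an exclusion-induced slack
        assert np.abs(z).max() < 4.5
        # and the policy effect visibly moves the target itself
        assert bundle.truth["targets"]["target_p_any_opioid"].min() < cfg.base_opioid_rate

    def test_absorbing_adoption_in_bundle_policy_table(self):
        cfg = small_cfg(adoption_hazard=0.2)
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        panel = pm.build_treatment_panel(bundle.policies, cfg.window)
        for p in cfg.policy_types:
            _, T = treatment_matrix(panel, p)
            assert (np.diff(T, axis=1) >= 0).all()


class TestSerialisation:
    def test_write_bundle_roundtrip(self, tmp_path):
        cfg = small_cfg(patients_per_state=10)
        bundle = pm.simulate_claims(cfg, pm.simulate_policy_adoption(cfg))
        paths = pm.write_bundle(bundle, tmp_path)
        assert set(paths) == {"claims", "diagnoses", "roster", "policies",
                              "covariates", "deaths", "truth", "targets"}
        back = pd.read_csv(paths["claims"], parse_dates=["fill_date"])
        assert len(back) == len(bundle.claims)
        import json
        truth = json.loads(paths["truth"].read_text())
        assert "true_effect_schedule" in truth
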