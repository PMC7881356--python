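"""Indicator engine: MME arithmetic, window rules, exclusions, aggregation."""

import numpy as np
import pandas as pd
import pytest

from conftest import mk_claims, mk_diagnoses, random_claims
from policymatch import claims as ci
from policymatch import reference
from policymatch.claims import IndicatorConfig
from policymatch.quarters import QuarterWindow


class TestDailyMME:
    def test_single_claim_matches_stated_formula(self, window12):
        # 5 mg/unit × (120 units / 30 days) × factor 1.5 = 30 MME/day
        c = mk_claims(dict(fill_date="2007-02-01", strength_per_unit=5.0,
                           quantity=120.0, days_supply=30, mme_factor=1.5))
        s = ci.daily_mme_series(c, window12)
        covered = s[(s.index >= "2007-02-01") & (s.index <= "2007-03-02")]
        assert np.allclose(covered, 30.0)
        assert s[s.index < "2007-02-01"].sum() == 0
        assert s[s.index > "2007-03-02"].sum() == 0

    def test_concurrent_claims_sum(self, window12):
        row = dict(fill_date="2007-02-01", strength_per_unit=5.0,
                   quantity=120.0, days_supply=30, mme_factor=1.5)
        s = ci.daily_mme_series(mk_claims(row, row), window12)
        assert s.loc["2007-02-15"] == 60.0

    def test_one_day_supply_covers_only_fill_date(self, window12):
        c = mk_claims(dict(fill_date="2007-05-10", days_supply=1, quantity=4.0))
        s = ci.daily_mme_series(c, window12)
        assert s.loc["2007-05-10"] > 0
        assert (s.drop(pd.Timestamp("2007-05-10")) == 0).all()

    def test_nonpositive_days_supply_rejected(self, window12, caplog):
        c = mk_claims(dict(fill_date="2007-02-01", days_supply=0))
        with caplog.at_level("WARNING"):
            s = ci.daily_mme_series(c, window12)
        assert (s == 0).all()
        assert "nonpositive days supply" in caplog.text

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_day_bruteforce(self, window12, seed):
        rng = np.random.default_rng(seed)
        c = random_claims(rng, 20, window12)
        fast = ci.daily_mme_series(c, window12).to_numpy()
        assert np.allclose(fast, reference.brute_daily_mme(c, window12))

    def test_order_invariance(self, window12, rng):
        c = random_claims(rng, 15, window12)
        shuffled = c.sample(frac=1, random_state=7).reset_index(drop=True)
        assert np.allclose(
            ci.daily_mme_series(c, window12).to_numpy(),
            ci.daily_mme_series(shuffled, window12).to_numpy(),
        )


class TestHighDoseFlag:
    def test_threshold_boundary(self, window12):
        daily = np.zeros(window12.n_days)
        daily[10] = 89.9
        assert not ci.flag_mme90(daily, window12).any()
        daily[10] = 90.0
        assert ci.flag_mme90(daily, window12)[0]  # day 10 is in quarter 0

    def test_flag_lands_in_quarter_of_violating_day(self, window12):
        daily = np.zeros(window12.n_days)
        daily[window12.quarter_day_bounds()[3, 0]] = 120.0
        flags = ci.flag_mme90(daily, window12)
        assert flags[3] and flags.sum() == 1


class TestDoctorShopping:
    def _stream(self, ids, start="2007-02-01", step=20):
        t0 = pd.Timestamp(start)
        return mk_claims(*[
            dict(fill_date=t0 + pd.Timedelta(days=step * k),
                 prescriber_id=f"D{d}", pharmacy_id=f"F{p}", days_supply=5)
            for k, (d, p) in enumerate(ids)
        ])

    def test_four_doctors_four_pharmacies_within_90_days(self, window12):
        c = self._stream([(1, 1), (2, 2), (3, 3), (4, 4)])
        assert ci.flag_doctor_shopping(c, window12).any()

    def test_conjunction_fails_with_three_pharmacies(self, window12):
        c = self._stream([(1, 1), (2, 2), (3, 3), (4, 1)])
        assert not ci.flag_doctor_shopping(c, window12).any()

    def test_span_longer_than_90_days_not_flagged(self, window12):
        c = self._stream([(1, 1), (2, 2), (3, 3), (4, 4)], step=31)  # 93-day span
        assert not ci.flag_doctor_shopping(c, window12).any()

    def test_missing_ids_ignored(self, window12, caplog):
        c = self._stream([(1, 1), (2, 2), (3, 3), (4, 4)])
        c.loc[3, "prescriber_id"] = np.nan
        with caplog.at_level("WARNING"):
            assert not ci.flag_doctor_shopping(c, window12).any()
        assert "missing prescriber/pharmacy" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_enumeration_oracle(self, window12, seed):
        rng = np.random.default_rng(100 + seed)
        c = random_claims(rng, 25, window12)
        fast = ci.flag_doctor_shopping(c, window12)
        brute = reference.brute_flag_doctor_shopping(c, window12)
        assert (fast == brute).all()


class TestOverlap:
    def test_adjacent_supplies_do_not_overlap(self, window12):
        c = mk_claims(
            dict(fill_date="2007-01-01", days_supply=30),
            dict(fill_date="2007-01-31", days_supply=30),
        )
        assert not ci.flag_overlap(c, window12).any()

    def test_one_shared_day_flags(self, window12):
        c = mk_claims(
            dict(fill_date="2007-01-01", days_supply=30),
            dict(fill_date="2007-01-30", days_supply=30),
        )
        assert ci.flag_overlap(c, window12)[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_interval_oracle(self, window12, seed):
        rng = np.random.default_rng(200 + seed)
        c = random_claims(rng, 20, window12)
        assert (ci.flag_overlap(c, window12)
                == reference.brute_flag_overlap(c, window12)).all()


class TestMAT:
    def test_buprenorphine_claim_flags(self, window12):
        c = mk_claims(dict(fill_date="2007-02-01", drug_class="mat"))
        assert ci.flag_mat(c, window12)[0]

    def test_methadone_excluded_by_default_included_by_switch(self, window12):
        c = mk_claims(dict(fill_date="2007-02-01", drug_class="methadone"))
        assert not ci.flag_mat(c, window12).any()
        assert ci.flag_mat(c, window12, methadone_as_mat=True)[0]


class TestExclusions:
    def test_cancer_excluded_oud_retained(self):
        dx = mk_diagnoses(
            dict(patient_id="A", code="C50.9"),
            dict(patient_id="B", code="F11.20"),
        )
        assert ci.exclude_cohort(dx) == {"A"}

    def test_unknown_icd_version_rejected_with_warning(self, caplog):
        dx = mk_diagnoses(dict(patient_id="A", code="C50.9", icd_version=11))
        with caplog.at_level("WARNING"):
            assert ci.exclude_cohort(dx) == set()
        assert "unknown ICD version" in caplog.text

    def test_planted_cancer_patients_exactly_excluded(self, rng):
        planted = {f"P{i}" for i in rng.choice(1000, 100, replace=False)}
        rows = [dict(patient_id=p, code="C50.9") for p in sorted(planted)]
        rows += [dict(patient_id=f"Q{i}", code="F11.20") for i in range(200)]
        assert ci.exclude_cohort(mk_diagnoses(*rows)) == planted

    def test_icd9_palliative_and_cancer_codes(self):
        dx = mk_diagnoses(
            dict(patient_id="A", code="174", icd_version=9, date="2010-01-01"),
            dict(patient_id="B", code="V66.7", icd_version=9, date="2010-01-01"),
        )
        assert ci.exclude_cohort(dx) == {"A", "B"}


class TestAggregation:
    def _roster(self, n, state="S01"):
        return pd.DataFrame({"state": state, "patient_id": [f"P{i}" for i in range(n)]})

    def test_three_of_ten_flagged_gives_point_three(self, window8):
        claims = mk_claims(*[
            dict(patient_id=f"P{i}", fill_date="2007-02-01") for i in range(3)
        ])
        table = ci.compute_indicators(claims, mk_diagnoses()[:0], self._roster(10),
                                      window8)
        assert table.loc[table["quarter"] == 0, "p_any_opioid"].iloc[0] == 0.3

    def test_all_enrollees_excluded_gives_missing_not_zero(self, window8):
        roster = self._roster(3)
        dx = mk_diagnoses(*[dict(patient_id=f"P{i}", code="C50.9") for i in range(3)])
        table = ci.compute_indicators(mk_claims()[:0], dx, roster, window8)
        assert table["p_any_opioid"].isna().all()
        assert (table["n_enrollees"] == 0).all()

    def test_empty_roster_produces_empty_table(self, window8):
        table = ci.compute_indicators(mk_claims()[:0], mk_diagnoses()[:0],
                                      self._roster(0), window8)
        assert len(table) == 0

    def test_proportions_bounded_and_monotone_in_flagged_patients(self, window8):
        base = [dict(patient_id=f"P{i}", fill_date="2007-02-01") for i in range(3)]
        t1 = ci.compute_indicators(mk_claims(*base), mk_diagnoses()[:0],
                                   self._roster(10), window8)
        extra = base + [dict(patient_id="P7", fill_date="2007-02-01")]
        t2 = ci.compute_indicators(mk_claims(*extra), mk_diagnoses()[:0],
                                   self._roster(10), window8)
        for t in (t1, t2):
            props = t[[c for c in t.columns if c.startswith("p_")]].to_numpy(float)
            assert np.nanmin(props) >= 0 and np.nanmax(props) <= 1
        assert (t2["p_any_opioid"] >= t1["p_any_opioid"]).all()

    def test_subset_denominator_config(self, window8):
        claims = mk_claims(
            dict(patient_id="P0", fill_date="2007-02-01"),
            dict(patient_id="P1", fill_date="2007-02-01", drug_class="mat"),
            dict(patient_id="P1", fill_date="2007-02-01"),
        )
        t_all = ci.compute_indicators(claims, mk_diagnoses()[:0], self._roster(4),
                                      window8)
        cfg = IndicatorConfig(subset_denominator="ever_opioid")
        t_sub = ci.compute_indicators(claims, mk_diagnoses()[:0], self._roster(4),
                                      window8, cfg)
        q0_all = t_all[t_all["quarter"] == 0].iloc[0]
        q0_sub = t_sub[t_sub["quarter"] == 0].iloc[0]
        assert q0_all["p_mat"] == 0.25   # 1 of 4 enrollees
        assert q0_sub["p_mat"] == 0.5    # 1 of 2 ever-opioid patients


def test_full_bundle_matches_bruteforce_exactly(window12):
    """All six indicators on a synthetic cohort equal the per-patient oracle."""
    from policymatch import SimConfig, simulate_claims, simulate_policy_adoption

    cfg = SimConfig(n_states=3, n_quarters=12, patients_per_state=60,
                    adoption_hazard=0.05, shopper_rate=0.03, seed=42)
    bundle = simulate_claims(cfg, simulate_policy_adoption(cfg))
    fast = ci.compute_indicators(bundle.claims, bundle.diagnoses, bundle.roster,
                                 cfg.window)
    brute = reference.brute_indicators(bundle.claims, bundle.diagnoses,
                                       bundle.roster, cfg.window)
    cols = ["p_any_opioid", "p_oud_overdose", "p_mme90",
            "p_doctor_shopping", "p_overlap", "p_mat"]
    fast = fast.sort_values(["state", "quarter"]).reset_index(drop=True)
    brute = brute.sort_values(["state", "quarter"]).reset_index(drop=True)
    for c in cols:
        assert np.allclose(fast[c], brute[c], equal_nan=True), c
    assert (fast["n_enrollees"] == brute["n_enrollees"]).all()
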