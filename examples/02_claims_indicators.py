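"""Compute the six prescription-opioid indicators for a synthetic cohort.

Each indicator is the proportion of eligible enrollees (cancer/palliative
patients excluded) flagged in a state-quarter: any opioid fill, OUD or
overdose diagnosis, a day at >=90 daily MME, doctor shopping (>=4
prescribers AND >=4 pharmacies within 90 days), overlapping prescriptions,
and medication-assisted treatment.
"""

from policymatch import SimConfig, compute_indicators, simulate_claims, \
    simulate_policy_adoption

cfg = SimConfig(n_states=4, n_quarters=12, patients_per_state=150,
                adoption_hazard=0.05, shopper_rate=0.01, seed=3)
bundle = simulate_claims(cfg, simulate_policy_adoption(cfg))
table = compute_indicators(bundle.claims, bundle.diagnoses, bundle.roster,
                           cfg.window)

cols = ["state", "quarter", "p_any_opioid", "p_mme90", "p_doctor_shopping",
        "p_overlap", "p_mat", "n_enrollees"]
print(table[table["state"] == "S01"][cols].head(8).to_string(index=False))
print()
print("mean any-opioid proportion:", round(table["p_any_opioid"].mean(), 4),
      "(generator target ~", cfg.base_opioid_rate, "before policy effects)")
# Proportions are per state-quarter; denominators exclude the cancer/
# palliative cohort, so n_enrollees can be below patients_per_state.
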