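"""Canonical validation studies for the estimator and pipeline.

These functions define the package's standard self-validation scenarios on
synthetic data with known truth:

* dual-route agreement between the production implementations and the
  brute-force reference route on small problems;
* closed-form limits (two-period DiD, fixed-effect pooling, two-study
  DerSimonian–Laird);
* parameter recovery of an injected lead-effect schedule;
* null calibration of bootstrap intervals and the significance classifier;
* qualitative sign reproduction of a supply-policy / harm-reduction-policy
  effect grid through the full claims → indicators → matching → pooling and
  deaths → rates → matching → pooling paths.

Problem sizes are chosen for a desk-scale single-CPU run; each function
documents its conditions and returns plain dictionaries of measured
quantities so callers can apply their own thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference
from .claims import compute_indicators
from .matching import (_att_profile_array, _first_adoption, _sets_array,
                       _uniform, bootstrap_ci)
from .meta import (classify_effect, pool_random_effects, pool_with_draws,
                   tau2_dersimonian_laird)
from .mortality import classify_death_records, deaths_to_rate
from .policies import build_treatment_panel, treatment_matrix
from .simulate import SimConfig, simulate_claims, simulate_policy_adoption, \
    simulate_state_outcomes

#: default injected lead profile: a ramp from no effect to −1 outcome unit
RAMP_DOWN = tuple(np.linspace(0.0, -1.0, 13))


def _panel_matrices(cfg: SimConfig, policy: str, outcome: str = "outcome"):
    pol = simulate_policy_adoption(cfg)
    out = simulate_state_outcomes(cfg, pol)
    panel = build_treatment_panel(pol, cfg.window)
    wt, T = treatment_matrix(panel, policy)
    wy = out.pivot(index="state", columns="quarter", values=outcome).reindex(wt.index)
    return wt, T, wy


def oracle_equivalence(seed: int = 0, n_draws: int = 5) -> dict:
    """Max discrepancy between production and brute-force routes.

    Random staggered panels of ≤6 states × ≤12 quarters for matched sets and
    per-set DiD, and a ~180-patient synthetic cohort for all six indicators.
    """
    rng = np.random.default_rng(seed)
    sets_equal = True
    att_max_diff = 0.0
    for _ in range(n_draws):
        S, Q = int(rng.integers(4, 7)), int(rng.integers(8, 13))
        T = np.zeros((S, Q), dtype=np.int8)
        for s in range(S):
            hit = np.flatnonzero(rng.random(Q) < 0.12)
            if len(hit):
                T[s, hit[0]:] = 1
        L = int(rng.integers(1, 4))
        fast = [(s, t, sorted(c)) for s, t, c in _sets_array(T, L)]
        brute = [(s, t, sorted(c)) for s, t, c in reference.brute_matched_sets(T, L)]
        sets_equal &= fast == brute
        Y = rng.normal(0, 1, (S, Q))
        wsets = _uniform(_sets_array(T, L))
        est, _ = _att_profile_array(wsets, Y, Q - 1, adopt=_first_adoption(T))
        for F in range(Q):
            b = reference.brute_att(
                [(s, t, list(c), list(w)) for s, t, c, w in wsets], Y, T, F)
            if np.isfinite(b) or np.isfinite(est[F]):
                att_max_diff = max(att_max_diff, abs(est[F] - b))

    cfg = SimConfig(n_states=3, n_quarters=12, patients_per_state=60,
                    adoption_hazard=0.05, shopper_rate=0.03, seed=seed)
    bundle = simulate_claims(cfg, simulate_policy_adoption(cfg))
    fast_ind = compute_indicators(bundle.claims, bundle.diagnoses, bundle.roster,
                                  cfg.window).sort_values(["state", "quarter"])
    brute_ind = reference.brute_indicators(
        bundle.claims, bundle.diagnoses, bundle.roster, cfg.window
    ).sort_values(["state", "quarter"])
    cols = ["p_any_opioid", "p_oud_overdose", "p_mme90",
            "p_doctor_shopping", "p_overlap", "p_mat"]
    ind_max_diff = float(np.nanmax(np.abs(
        fast_ind[cols].to_numpy(float) - brute_ind[cols].to_numpy(float))))
    return {
        "matched_sets_equal": bool(sets_equal),
        "att_max_abs_diff": float(att_max_diff),
        "indicators_max_abs_diff": ind_max_diff,
        "n_patients": int(len(bundle.roster)),
    }


def closed_form_checks() -> dict:
    """Agreement with textbook closed forms."""
    # two-unit two-period DiD
    T = np.zeros((2, 4), dtype=np.int8)
    T[0, 2:] = 1
    Y = np.array([[1.0, 1.0, 6.0, 6.0], [2.0, 2.0, 4.0, 4.0]])
    sets = _uniform(_sets_array(T, 1))
    est, _ = _att_profile_array(sets, Y, 0, adopt=_first_adoption(T))
    did_diff = abs(est[0] - reference.classical_did_2x2(1, 6, 2, 4))
    # tau2=0 pooling = fixed-effect inverse-variance mean
    y, se = [0.2, 0.3, 0.25, 0.22], [0.1, 0.1, 0.1, 0.1]
    p = pool_random_effects(y, se, method="reml")
    fe_diff = abs(p.mean_effect - reference.fixed_effect_mean(y, se))
    # two-study DerSimonian–Laird: Q=2, C=1 → tau2=1
    tau2 = tau2_dersimonian_laird(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
    return {
        "did_2x2_abs_diff": float(did_diff),
        "fixed_effect_abs_diff": float(fe_diff),
        "dl_tau2_abs_err": float(abs(tau2 - 1.0)),
    }


def recovery_study(
    n_reps: int = 500,
    seed: int = 0,
    schedule=RAMP_DOWN,
    policy: str = "pdmp_mandatory",
) -> dict:
    """Bias of the lead profile against an injected schedule.

    Conditions: 50 states × 48 quarters, adoption hazard 0.02/quarter,
    noise sd 1, pre-trend slope sd 0.02, uniform set weights (adoption in
    the generator is covariate-independent). Returns per-lead mean, MCSE,
    and the correlation of the mean profile with the truth.
    """
    sched = np.asarray(schedule, float)
    reps = []
    for r in range(n_reps):
        cfg = SimConfig(
            n_states=50, n_quarters=48, patients_per_state=0,
            adoption_hazard=0.02, noise_sd=1.0, pre_trend_slope_sd=0.02,
            true_effect_schedule={policy: {"outcome": sched}},
            seed=(seed * 100_003 + r) % 2**31,
        )
        wt, T, wy = _panel_matrices(cfg, policy)
        sets = _uniform(_sets_array(T, 4))
        est, _ = _att_profile_array(sets, wy.to_numpy(float), len(sched) - 1,
                                    adopt=_first_adoption(T))
        reps.append(est)
    reps = np.asarray(reps)
    mean = np.nanmean(reps, axis=0)
    mcse = np.nanstd(reps, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(reps), axis=0))
    return {
        "truth": sched.tolist(),
        "mean_att": mean.tolist(),
        "mcse": mcse.tolist(),
        "max_abs_bias_in_mcse": float(np.max(np.abs(mean - sched) / mcse)),
        "max_abs_bias": float(np.max(np.abs(mean - sched))),
        "profile_correlation": float(np.corrcoef(mean, sched)[0, 1]),
        "n_reps": n_reps,
    }


def null_calibration_study(
    n_reps: int = 300,
    B: int = 200,
    seed: int = 0,
    coverage_lead: int = 4,
    policy: str = "pdmp_mandatory",
) -> dict:
    """Coverage of bootstrap CIs and classifier false-flag rate under the null.

    Same panel conditions as :func:`recovery_study` with zero injected
    effect. Coverage is measured for the mid-profile lead CI; the flag rate
    applies the sign/significance classifier to the bootstrap-pooled effect.
    """
    covered, flagged = [], []
    for r in range(n_reps):
        cfg = SimConfig(
            n_states=50, n_quarters=48, patients_per_state=0,
            adoption_hazard=0.02, noise_sd=1.0, pre_trend_slope_sd=0.02,
            seed=(seed * 100_003 + r) % 2**31,
        )
        wt, T, wy = _panel_matrices(cfg, policy)
        ests, draws = bootstrap_ci(
            wt, wy, L=4, f_max=12, B=B, seed=(seed * 7 + 13 * r) % 2**31,
            method="uniform", return_draws=True,
        )
        e = ests[coverage_lead]
        if np.isfinite(e.ci_low):
            covered.append(e.ci_low <= 0.0 <= e.ci_high)
        pooled = pool_with_draws([x.estimate for x in ests],
                                 [x.se for x in ests], draws)
        flagged.append(pooled.significant)
    return {
        "coverage": float(np.mean(covered)),
        "significant_rate": float(np.mean(flagged)),
        "n_reps": n_reps,
        "B": B,
        "coverage_lead": coverage_lead,
    }


# configuration of the qualitative sign-reproduction study: a
# supply-controlling policy suppresses misuse indicators while a
# harm-reduction policy raises illicit-drug death rates
SIGN_STUDY_EXPECTED = {
    ("pdmp_mandatory", "p_any_opioid"): "significant-negative",
    ("pdmp_mandatory", "p_mme90"): "significant-negative",
    ("naloxone_access", "heroin_T401"): "significant-positive",
    ("naloxone_access", "synthetic_T404"): "significant-positive",
}


def sign_pattern_study(seed: int = 0, patients_per_state: int = 400,
                       n_states: int = 40, B: int = 200) -> dict:
    """Full-pipeline qualitative reproduction of the effect-sign grid.

    A mandatory-PDMP-style supply policy is injected with negative effects
    on the any-opioid and high-dose fill probabilities; a naloxone-style
    harm-reduction policy with positive effects on heroin and synthetic
    overdose death rates. The claims → indicators and deaths → rates paths
    are run end to end, matched and pooled, and each evaluated (policy,
    outcome) cell's shading label is compared with the injected pattern:
    injected cells must carry the right significant label, non-injected
    cells must not be significant.
    """
    cfg = SimConfig(
        n_states=n_states, n_quarters=48, patients_per_state=patients_per_state,
        adoption_hazard=0.02, high_dose_rate=0.05,
        claim_effect_schedule={"pdmp_mandatory": np.linspace(-0.01, -0.05, 13)},
        high_dose_effect_schedule={"pdmp_mandatory": np.linspace(-0.005, -0.03, 13)},
        death_effect_schedule={"naloxone_access": {
            "heroin_T401": np.linspace(100, 400, 13),
            "synthetic_T404": np.linspace(150, 500, 13),
        }},
        seed=seed % 2**31,
    )
    policies_tbl = simulate_policy_adoption(cfg)
    bundle = simulate_claims(cfg, policies_tbl)
    indicators = compute_indicators(bundle.claims, bundle.diagnoses,
                                    bundle.roster, cfg.window)
    monthly = classify_death_records(bundle.deaths, cfg.window)
    rates = deaths_to_rate(monthly, bundle.covariates, cfg.window)
    panel = build_treatment_panel(policies_tbl, cfg.window)

    def outcome_wide(name):
        if name.startswith("p_"):
            return indicators.pivot(index="state", columns="quarter", values=name)
        sub = rates[rates["cause_category"] == name]
        return sub.pivot(index="state", columns="quarter", values="rate_per_300m")

    labels, grid = {}, []
    rng = np.random.default_rng([seed % 2**31, 51])
    for policy in ("pdmp_mandatory", "naloxone_access"):
        wt, _ = treatment_matrix(panel, policy)
        for outcome in ("p_any_opioid", "p_mme90", "heroin_T401", "synthetic_T404"):
            wy = outcome_wide(outcome).reindex(wt.index)
            ests, draws = bootstrap_ci(wt, wy, L=4, f_max=12, B=B, seed=rng,
                                       method="uniform", return_draws=True)
            pooled = pool_with_draws([e.estimate for e in ests],
                                     [e.se for e in ests], draws,
                                     policy, outcome)
            label = classify_effect(pooled)
            labels[(policy, outcome)] = label
            expected = SIGN_STUDY_EXPECTED.get((policy, outcome))
            agree = (label == expected if expected is not None
                     else not pooled.significant)
            grid.append({
                "policy": policy, "outcome": outcome,
                "mean_effect": pooled.mean_effect,
                "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                "label": label, "expected": expected or "null",
                "agrees": bool(agree),
            })
    frame = pd.DataFrame(grid)
    return {
        "grid": frame,
        "n_cells": int(len(frame)),
        "n_agree": int(frame["agrees"].sum()),
        "agreement": float(frame["agrees"].mean()),
        "injected_all_correct": bool(
            frame[frame["expected"] != "null"]["agrees"].all()),
    }
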