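"""Brute-force reference implementations for validation.

Everything here recomputes a quantity the optimised modules produce, by the
most literal enumeration possible (per-day loops, pairwise interval checks,
exhaustive matched-set scans). These functions share no code with the
production paths; they exist so the fast implementations can be checked
against an independent route on small problems. They are deliberately slow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import icd
from .quarters import QuarterWindow


# ---------------------------------------------------------------------------
# claims indicators
# ---------------------------------------------------------------------------

def brute_daily_mme(claims: pd.DataFrame, window: QuarterWindow) -> np.ndarray:
    """Per-day MME by looping every claim over every day it covers."""
    out = np.zeros(window.n_days)
    for rec in claims.itertuples(index=False):
        if rec.drug_class != "opioid" or rec.days_supply <= 0:
            continue
        dose = rec.strength_per_unit * (rec.quantity / rec.days_supply) * rec.mme_factor
        d0 = int(window.day_index(np.datetime64(rec.fill_date, "D")))
        for d in range(d0, d0 + int(rec.days_supply)):
            if 0 <= d < window.n_days:
                out[d] += dose
    return out


def _quarter_of_day(window: QuarterWindow, day: int) -> int:
    return int(window.quarter_of_day([day])[0])


def brute_flag_mme90(claims, window, threshold=90.0) -> np.ndarray:
    daily = brute_daily_mme(claims, window)
    out = np.zeros(window.n_quarters, dtype=bool)
    for d in range(window.n_days):
        if daily[d] >= threshold:
            out[_quarter_of_day(window, d)] = True
    return out


def brute_flag_overlap(claims, window) -> np.ndarray:
    """Pairwise interval-intersection scan over all opioid claim pairs."""
    ivals = []
    for rec in claims.itertuples(index=False):
        if rec.drug_class != "opioid" or rec.days_supply <= 0:
            continue
        d0 = int(window.day_index(np.datetime64(rec.fill_date, "D")))
        ivals.append((d0, d0 + int(rec.days_supply) - 1))
    out = np.zeros(window.n_quarters, dtype=bool)
    for i in range(len(ivals)):
        for j in range(i + 1, len(ivals)):
            lo = max(ivals[i][0], ivals[j][0])
            hi = min(ivals[i][1], ivals[j][1])
            for d in range(lo, hi + 1):
                if 0 <= d < window.n_days:
                    out[_quarter_of_day(window, d)] = True
    return out


def brute_flag_doctor_shopping(claims, window, k_doctors=4, k_pharmacies=4,
                               window_days=90) -> np.ndarray:
    """Enumerate the window ending at every claim date and count uniques."""
    recs = [
        r for r in claims.itertuples(index=False)
        if r.drug_class == "opioid" and r.days_supply > 0
        and not (pd.isna(r.prescriber_id) or pd.isna(r.pharmacy_id))
    ]
    days = [int(window.day_index(np.datetime64(r.fill_date, "D"))) for r in recs]
    out = np.zeros(window.n_quarters, dtype=bool)
    for i in range(len(recs)):
        docs, pharms = set(), set()
        for j in range(len(recs)):
            if days[i] - (window_days - 1) <= days[j] <= days[i]:
                docs.add(recs[j].prescriber_id)
                pharms.add(recs[j].pharmacy_id)
        if len(docs) >= k_doctors and len(pharms) >= k_pharmacies:
            q = _quarter_of_day(window, min(days[i], window.n_days - 1))
            if 0 <= days[i] < window.n_days:
                out[q] = True
    return out


def brute_indicators(claims, diagnoses, roster, window,
                     mme_threshold=90.0, methadone_as_mat=False) -> pd.DataFrame:
    """All six state-quarter proportions by direct per-patient recomputation."""
    excluded = set()
    categories = {}
    for rec in diagnoses.itertuples(index=False):
        try:
            cat = icd.categorize_diagnosis(rec.code, rec.icd_version)
        except ValueError:
            continue
        if cat in ("cancer", "palliative"):
            excluded.add(rec.patient_id)
        categories.setdefault(rec.patient_id, []).append((rec.date, cat))

    mat_classes = {"mat", "methadone"} if methadone_as_mat else {"mat"}
    per_patient = {}
    for pid, sub in claims.groupby("patient_id"):
        if pid in excluded:
            continue
        flags = np.zeros((window.n_quarters, 6), dtype=bool)
        for rec in sub.itertuples(index=False):
            q = int(window.quarter_of(np.datetime64(rec.fill_date, "ns"))[0])
            if not 0 <= q < window.n_quarters:
                continue
            if rec.drug_class == "opioid" and rec.days_supply > 0:
                flags[q, 0] = True
            if rec.drug_class in mat_classes:
                flags[q, 5] = True
        flags[:, 2] = brute_flag_mme90(sub, window, mme_threshold)
        flags[:, 3] = brute_flag_doctor_shopping(sub, window)
        flags[:, 4] = brute_flag_overlap(sub, window)
        per_patient[pid] = flags
    for pid, recs in categories.items():
        if pid in excluded:
            continue
        for date, cat in recs:
            if cat in ("oud", "overdose"):
                q = int(window.quarter_of(np.datetime64(date, "ns"))[0])
                if 0 <= q < window.n_quarters:
                    per_patient.setdefault(
                        pid, np.zeros((window.n_quarters, 6), dtype=bool)
                    )[q, 1] = True

    state_of = dict(zip(roster["patient_id"], roster["state"]))
    ever_opioid = {
        pid for pid, f in per_patient.items() if f[:, 0].any()
    }
    states = sorted(roster["state"].unique())
    denom = {
        s: sum(1 for p in roster["patient_id"] if state_of[p] == s and p not in excluded)
        for s in states
    }
    names = ["p_any_opioid", "p_oud_overdose", "p_mme90",
             "p_doctor_shopping", "p_overlap", "p_mat"]
    rows = []
    for s in states:
        for q in range(window.n_quarters):
            row = [s, q]
            for k, name in enumerate(names):
                cnt = 0
                for pid, f in per_patient.items():
                    if state_of.get(pid) != s or not f[q, k]:
                        continue
                    if k > 0 and pid not in ever_opioid:
                        continue
                    cnt += 1
                row.append(cnt / denom[s] if denom[s] > 0 else np.nan)
            row.append(denom[s])
            rows.append(row)
    return pd.DataFrame(rows, columns=["state", "quarter", *names, "n_enrollees"])


# ---------------------------------------------------------------------------
# panel matching
# ---------------------------------------------------------------------------

def brute_matched_sets(T: np.ndarray, L: int) -> list[tuple[int, int, list[int]]]:
    """Exhaustive scan over every (state, t, candidate-control) triple."""
    S, Q = T.shape
    out = []
    for s in range(S):
        for t in range(Q):
            if not (T[s, t] == 1 and (t == 0 or T[s, t - 1] == 0)):
                continue  # not a 0→1 switch at t
            if t < L:
                continue
            controls = []
            for c in range(S):
                if c == s:
                    continue
                same_history = all(T[c, t - ell] == T[s, t - ell] for ell in range(1, L + 1))
                if same_history and T[c, t] == 0:
                    controls.append(c)
            out.append((s, t, controls))
    return out


def brute_att(sets, Y: np.ndarray, T: np.ndarray, F: int) -> float:
    """Average per-set DiD at one lead, with equal weighting of sets.

    A control still counts at lead F only if it is untreated at t+F;
    surviving weights are renormalised, and a set with no clean control is
    dropped at this lead.
    """
    Q = Y.shape[1]
    vals = []
    for s, t, controls, weights in sets:
        if t + F >= Q:
            continue
        kept = [(c, w) for c, w in zip(controls, weights) if T[c, t + F] == 0]
        wsum = sum(w for _, w in kept)
        if not kept or wsum == 0:
            continue
        d_tr = Y[s, t + F] - Y[s, t - 1]
        d_c = sum(w * (Y[c, t + F] - Y[c, t - 1]) for c, w in kept) / wsum
        vals.append(d_tr - d_c)
    return float(np.mean(vals)) if vals else float("nan")


def classical_did_2x2(y_treated_pre, y_treated_post, y_control_pre, y_control_post) -> float:
    """Textbook two-unit two-period difference-in-differences."""
    return (y_treated_post - y_treated_pre) - (y_control_post - y_control_pre)


def fixed_effect_mean(estimates, ses) -> float:
    """Inverse-variance weighted mean (the tau²=0 pooling limit)."""
    y = np.asarray(estimates, float)
    w = 1.0 / np.asarray(ses, float) ** 2
    return float(np.sum(w * y) / np.sum(w))
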