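"""Prescription-opioid misuse indicators from patient-level claims.

Six patient-level indicators are computed per quarter and aggregated to
state × quarter proportions:

* ``p_any_opioid`` — any opioid fill in the quarter;
* ``p_oud_overdose`` — an opioid-use-disorder or overdose diagnosis;
* ``p_mme90`` — any day in the quarter at or above 90 daily morphine
  milligram equivalents (MME), where a fill contributes
  strength_per_unit × (quantity / days_supply) × MME conversion factor
  to every day of its supply interval and concurrent fills sum;
* ``p_doctor_shopping`` — opioid fills from ≥4 unique prescribers AND ≥4
  unique pharmacies within some 90-day window ending in the quarter;
* ``p_overlap`` — ≥1 day in the quarter covered by two distinct opioid
  prescriptions;
* ``p_mat`` — any medication-assisted-treatment fill (buprenorphine-based
  agents or naltrexone; methadone optionally included via config).

Patients with any cancer or palliative-care diagnosis are excluded from
numerators and denominators. The denominator is the eligible enrollee
roster; the five non-``any_opioid`` indicators restrict numerator
eligibility to patients who ever received an opioid during the window
(the denominator convention is configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import icd
from .quarters import QuarterWindow

logger = logging.getLogger(__name__)

INDICATORS = (
    "any_opioid", "oud_overdose", "mme90", "doctor_shopping", "overlap", "mat",
)

CLAIMS_SCHEMA = [
    "patient_id", "state", "fill_date", "days_supply", "quantity",
    "strength_per_unit", "mme_factor", "drug_class", "prescriber_id", "pharmacy_id",
]
DIAGNOSES_SCHEMA = ["patient_id", "date", "code", "icd_version"]


@dataclass(frozen=True)
class IndicatorConfig:
    """Thresholds and conventions for the indicator engine."""

    mme_threshold: float = 90.0
    shopping_k_doctors: int = 4
    shopping_k_pharmacies: int = 4
    shopping_window_days: int = 90
    methadone_as_mat: bool = False
    #: denominator for the five subset indicators: eligible enrollees
    #: (default) or only patients who ever received an opioid in the window
    subset_denominator: str = "enrollees"
    code_map: dict | None = None


def exclude_cohort(diagnoses: pd.DataFrame, code_map: dict | None = None) -> set:
    """Patient ids with ≥1 cancer or palliative-care diagnosis record.

    Records with an unknown ICD version are rejected with a warning.
    """
    excluded: set = set()
    for rec in diagnoses.itertuples(index=False):
        try:
            cat = icd.categorize_diagnosis(rec.code, rec.icd_version, code_map)
        except ValueError as exc:
            logger.warning("rejecting diagnosis record: %s", exc)
            continue
        if cat in ("cancer", "palliative"):
            excluded.add(rec.patient_id)
    return excluded


def categorize_diagnoses(diagnoses: pd.DataFrame, code_map: dict | None = None) -> pd.Series:
    """Vectorised category per diagnosis row ('__invalid__' for bad versions)."""
    cache: dict[tuple, str] = {}
    out = np.empty(len(diagnoses), dtype=object)
    for i, (code, ver) in enumerate(zip(diagnoses["code"], diagnoses["icd_version"])):
        key = (code, ver)
        if key not in cache:
            try:
                cache[key] = icd.categorize_diagnosis(code, ver, code_map)
            except ValueError:
                cache[key] = "__invalid__"
        out[i] = cache[key]
    return pd.Series(out, index=diagnoses.index)


# ---------------------------------------------------------------------------
# per-patient primitives
# ---------------------------------------------------------------------------

def _valid_opioid_claims(claims: pd.DataFrame) -> pd.DataFrame:
    op = claims[claims["drug_class"] == "opioid"]
    bad = op["days_supply"] <= 0
    if bad.any():
        logger.warning("rejecting %d opioid claims with nonpositive days supply", int(bad.sum()))
        op = op[~bad]
    return op


def daily_mme_series(claims: pd.DataFrame, window: QuarterWindow) -> pd.Series:
    """Daily morphine-milligram-equivalent series for one patient.

    Each opioid claim contributes
    ``strength_per_unit × (quantity / days_supply) × mme_factor`` to every
    day of its inclusive supply interval
    [fill_date, fill_date + days_supply − 1]; concurrent claims sum.
    Returns a Series indexed by calendar date covering the window, in mg
    morphine equivalent per day. Input order is irrelevant.
    """
    arr = _daily_mme_array(claims, window)
    idx = pd.date_range(window.start_date, periods=window.n_days, freq="D")
    return pd.Series(arr, index=idx, name="daily_mme")


def _daily_mme_array(claims: pd.DataFrame, window: QuarterWindow) -> np.ndarray:
    op = _valid_opioid_claims(claims)
    delta = np.zeros(window.n_days + 1)
    if len(op):
        start = window.day_index(op["fill_date"].to_numpy())
        dur = op["days_supply"].to_numpy(dtype=int)
        dose = (
            op["strength_per_unit"].to_numpy(float)
            * op["quantity"].to_numpy(float) / dur
            * op["mme_factor"].to_numpy(float)
        )
        lo = np.clip(start, 0, window.n_days)
        hi = np.clip(start + dur, 0, window.n_days)
        np.add.at(delta, lo, dose)
        np.add.at(delta, hi, -dose)
    return np.cumsum(delta[:-1])


def _quarter_any(day_flags: np.ndarray, qbounds: np.ndarray) -> np.ndarray:
    # reduceat over quarter start offsets gives a per-quarter maximum
    return np.maximum.reduceat(day_flags.astype(np.int8), qbounds[:, 0]).astype(bool)


def flag_mme90(daily: np.ndarray, window: QuarterWindow,
               threshold: float = 90.0) -> np.ndarray:
    """True for each quarter containing ≥1 day with daily MME ≥ threshold."""
    return _quarter_any(daily >= threshold, window.quarter_day_bounds())


def flag_overlap(claims: pd.DataFrame, window: QuarterWindow) -> np.ndarray:
    """True for each quarter with ≥1 day covered by two distinct opioid claims."""
    op = _valid_opioid_claims(claims)
    delta = np.zeros(window.n_days + 1, dtype=int)
    if len(op):
        start = window.day_index(op["fill_date"].to_numpy())
        dur = op["days_supply"].to_numpy(dtype=int)
        np.add.at(delta, np.clip(start, 0, window.n_days), 1)
        np.add.at(delta, np.clip(start + dur, 0, window.n_days), -1)
    coverage = np.cumsum(delta[:-1])
    return _quarter_any(coverage >= 2, window.quarter_day_bounds())


def flag_doctor_shopping(
    claims: pd.DataFrame,
    window: QuarterWindow,
    k_doctors: int = 4,
    k_pharmacies: int = 4,
    window_days: int = 90,
) -> np.ndarray:
    """True for each quarter where a window of ``window_days`` ending in that
    quarter holds opioid claims from ≥k unique prescribers AND pharmacies.

    Windows are anchored at claim dates (the window ending at each fill is
    examined), which detects every violating span. Claims with a missing
    prescriber or pharmacy id are ignored for this flag.
    """
    op = _valid_opioid_claims(claims)
    missing = op["prescriber_id"].isna() | op["pharmacy_id"].isna()
    if missing.any():
        logger.warning("ignoring %d claims with missing prescriber/pharmacy ids",
                       int(missing.sum()))
        op = op[~missing]
    out = np.zeros(window.n_quarters, dtype=bool)
    if len(op) < max(k_doctors, k_pharmacies):
        return out
    op = op.sort_values("fill_date")
    days = window.day_index(op["fill_date"].to_numpy())
    docs = op["prescriber_id"].to_numpy()
    pharms = op["pharmacy_id"].to_numpy()
    qs = window.quarter_of(op["fill_date"].to_numpy())
    j = 0
    for i in range(len(op)):
        while days[j] < days[i] - (window_days - 1):
            j += 1
        if (len(set(docs[j : i + 1])) >= k_doctors
                and len(set(pharms[j : i + 1])) >= k_pharmacies):
            if 0 <= qs[i] < window.n_quarters:
                out[qs[i]] = True
    return out


def flag_mat(claims: pd.DataFrame, window: QuarterWindow,
             methadone_as_mat: bool = False) -> np.ndarray:
    """True for each quarter with ≥1 medication-assisted-treatment fill."""
    mat_classes = {"mat", "methadone"} if methadone_as_mat else {"mat"}
    m = claims[claims["drug_class"].isin(mat_classes)]
    out = np.zeros(window.n_quarters, dtype=bool)
    if len(m):
        qs = window.quarter_of(m["fill_date"].to_numpy())
        qs = qs[(qs >= 0) & (qs < window.n_quarters)]
        out[qs] = True
    return out


def flag_any_opioid(claims: pd.DataFrame, window: QuarterWindow) -> np.ndarray:
    op = _valid_opioid_claims(claims)
    out = np.zeros(window.n_quarters, dtype=bool)
    if len(op):
        qs = window.quarter_of(op["fill_date"].to_numpy())
        qs = qs[(qs >= 0) & (qs < window.n_quarters)]
        out[qs] = True
    return out


# ---------------------------------------------------------------------------
# cohort-level engine
# ---------------------------------------------------------------------------

def compute_patient_flags(
    claims: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: QuarterWindow,
    config: IndicatorConfig = IndicatorConfig(),
) -> pd.DataFrame:
    """Long per-patient flag table: patient_id, quarter, one bool per indicator.

    Only patients with ≥1 claim or qualifying diagnosis produce rows; absent
    rows mean all-false. Exclusions are NOT applied here (see
    :func:`aggregate_state_quarter`).
    """
    rows: dict[tuple, np.ndarray] = {}
    nq = window.n_quarters

    def block(pid):
        return rows.setdefault(pid, np.zeros((nq, len(INDICATORS)), dtype=bool))

    for pid, sub in claims.groupby("patient_id", sort=True):
        b = block(pid)
        b[:, 0] |= flag_any_opioid(sub, window)
        daily = _daily_mme_array(sub, window)
        b[:, 2] |= flag_mme90(daily, window, config.mme_threshold)
        b[:, 3] |= flag_doctor_shopping(
            sub, window, config.shopping_k_doctors, config.shopping_k_pharmacies,
            config.shopping_window_days,
        )
        b[:, 4] |= flag_overlap(sub, window)
        b[:, 5] |= flag_mat(sub, window, config.methadone_as_mat)

    if len(diagnoses):
        cats = categorize_diagnoses(diagnoses, config.code_map)
        dx = diagnoses[cats.isin(["oud", "overdose"])]
        if len(dx):
            qs = window.quarter_of(dx["date"].to_numpy())
            for pid, q in zip(dx["patient_id"], qs):
                if 0 <= q < nq:
                    block(pid)[q, 1] = True

    if not rows:
        return pd.DataFrame(columns=["patient_id", "quarter", *INDICATORS])
    parts = []
    for pid, b in rows.items():
        nz = np.flatnonzero(b.any(axis=1))
        if len(nz) == 0:
            continue
        df = pd.DataFrame(b[nz], columns=list(INDICATORS))
        df.insert(0, "quarter", nz)
        df.insert(0, "patient_id", pid)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["patient_id", "quarter", *INDICATORS])
    return pd.concat(parts, ignore_index=True)


def aggregate_state_quarter(
    patient_flags: pd.DataFrame,
    roster: pd.DataFrame,
    excluded: set,
    window: QuarterWindow,
    config: IndicatorConfig = IndicatorConfig(),
) -> pd.DataFrame:
    """State × quarter indicator proportions.

    ``roster`` (state, patient_id) is the enrollee universe; excluded
    patients are dropped from numerators and denominators. Zero-denominator
    cells yield missing proportions (not zero). Numerator eligibility for
    the five subset indicators is restricted to ever-opioid patients;
    their denominator follows ``config.subset_denominator``.
    """
    states = sorted(roster["state"].unique())
    if not states:
        return pd.DataFrame(
            columns=["state", "quarter", *(f"p_{n}" for n in INDICATORS), "n_enrollees"]
        )
    roster = roster[~roster["patient_id"].isin(excluded)]
    flags = patient_flags[~patient_flags["patient_id"].isin(excluded)]

    ever_opioid = set(flags.loc[flags["any_opioid"], "patient_id"])
    denom_all = roster.groupby("state")["patient_id"].nunique()
    denom_sub = (
        roster[roster["patient_id"].isin(ever_opioid)]
        .groupby("state")["patient_id"].nunique()
        if config.subset_denominator == "ever_opioid" else denom_all
    )

    flags = flags.merge(roster, on="patient_id", how="inner")
    grid = pd.MultiIndex.from_product(
        [states, range(window.n_quarters)], names=["state", "quarter"]
    )
    out = pd.DataFrame(index=grid).reset_index()
    counts = flags.groupby(["state", "quarter"])[list(INDICATORS)].sum()
    subset_mask = flags["patient_id"].isin(ever_opioid)
    counts_sub = (
        flags[subset_mask].groupby(["state", "quarter"])[list(INDICATORS)].sum()
    )
    for name in INDICATORS:
        num = (counts if name == "any_opioid" else counts_sub).get(
            name, pd.Series(dtype=float)
        )
        den = denom_all if name == "any_opioid" else denom_sub
        num = num.reindex(grid, fill_value=0).to_numpy(dtype=float)
        d = den.reindex(out["state"]).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(np.nan_to_num(d) > 0, num / d, np.nan)
        if np.isnan(p).any():
            logger.warning("zero denominator for %s in %d state-quarters",
                           name, int(np.isnan(p).sum()))
        out[f"p_{name}"] = p
    out["n_enrollees"] = denom_all.reindex(out["state"]).fillna(0).to_numpy(int)
    return out


def compute_indicators(
    claims: pd.DataFrame,
    diagnoses: pd.DataFrame,
    roster: pd.DataFrame,
    window: QuarterWindow,
    config: IndicatorConfig = IndicatorConfig(),
) -> pd.DataFrame:
    """End-to-end: exclusions → per-patient flags → state-quarter proportions."""
    excluded = exclude_cohort(diagnoses, config.code_map)
    flags = compute_patient_flags(claims, diagnoses, window, config)
    return aggregate_state_quarter(flags, roster, excluded, window, config)
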