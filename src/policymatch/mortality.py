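"""Overdose-death classification and monthly-count recovery.

Three steps mirror how state mortality series are assembled from vital
statistics: (1) classify each death record into overlapping cause
categories from its underlying-cause code and contributing T40.x codes;
(2) recover monthly counts from a grand total plus leave-one-month-out
totals (the offline analogue of repeated aggregate queries against a
public mortality database); (3) convert state–quarter counts into rates
per 300 million population, the outcome scale used for the mortality
difference-in-differences analysis.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from . import icd
from .quarters import QuarterWindow

logger = logging.getLogger(__name__)

PER_POPULATION = 300_000_000  # effect sizes are reported per 300 million people


def classify_death(underlying_cause: str, contributing_codes: Iterable[str] = ()) -> set[str]:
    """Cause categories for one death record.

    Returns the empty set when the underlying cause is not a drug-overdose
    code; otherwise ``{"all_drug"}`` plus one category per distinct matching
    contributing T40.x code. Categories may overlap (polysubstance deaths
    count under every involved drug), so per-category counts need not sum to
    the all-drug count.
    """
    if not str(underlying_cause).strip():
        raise ValueError("underlying cause must be nonempty")
    if not icd.is_overdose_underlying(underlying_cause):
        return set()
    cats = {"all_drug"}
    for code in contributing_codes:
        cat = icd.t_code_category(code)
        if cat is not None:
            cats.add(cat)
    return cats


def classify_death_records(deaths: pd.DataFrame, window: QuarterWindow) -> pd.DataFrame:
    """Record-level deaths → MonthlyDeathCounts table.

    ``deaths`` columns: state, year, month, underlying_cause,
    contributing_codes (semicolon-separated T-codes, possibly empty).
    Malformed ICD strings cause the record to be skipped with a log entry.
    Output columns: state, month (window index), cause_category, count;
    every (state, month-in-window, category) combination is present.
    """
    rows = []
    for rec in deaths.itertuples(index=False):
        contrib = [c for c in str(getattr(rec, "contributing_codes", "") or "").split(";") if c]
        try:
            cats = classify_death(rec.underlying_cause, contrib)
        except ValueError as exc:
            logger.warning("skipping malformed death record: %s", exc)
            continue
        m = window.month_index(rec.year, rec.month)
        for cat in cats:
            rows.append((rec.state, m, cat))
    states = sorted(deaths["state"].unique())
    full = pd.MultiIndex.from_product(
        [states, range(window.n_months), icd.CAUSE_CATEGORIES],
        names=["state", "month", "cause_category"],
    )
    if rows:
        counts = (
            pd.DataFrame(rows, columns=["state", "month", "cause_category"])
            .query("0 <= month < @window.n_months")
            .groupby(["state", "month", "cause_category"])
            .size()
        )
    else:
        counts = pd.Series(dtype=int)
    out = counts.reindex(full, fill_value=0).rename("count").reset_index()
    return out


def recover_monthly_counts(
    total: int, leave_one_out_totals: Mapping[int, int] | pd.Series
) -> pd.Series:
    """Recover per-month counts by subtraction: count(m) = total − total_excluding_m.

    When the months partition the whole window the recovered counts sum back
    to ``total`` exactly. Any leave-one-out total exceeding the grand total is
    an inconsistency and raises.
    """
    loo = pd.Series(dict(leave_one_out_totals)).sort_index()
    if (loo > total).any():
        bad = loo[loo > total].index.tolist()
        raise ValueError(f"leave-one-out totals exceed grand total for months {bad}")
    return (total - loo).astype(loo.dtype)


def leave_one_out_totals(monthly: pd.Series | np.ndarray) -> tuple[int, pd.Series]:
    """Summarise a monthly series the way an aggregate-only interface exposes it.

    Returns the grand total and the map month → total-excluding-that-month.
    This is the forward direction that :func:`recover_monthly_counts` inverts.
    """
    s = pd.Series(monthly)
    total = int(s.sum())
    return total, (total - s).astype(int)


def deaths_to_rate(
    monthly_counts: pd.DataFrame,
    population: pd.DataFrame,
    window: QuarterWindow,
) -> pd.DataFrame:
    """State × quarter death rate per 300 million people, by cause category.

    ``monthly_counts``: state, month (window index), cause_category, count.
    ``population``: state, quarter, population (the state-quarter covariate).
    Rate = (quarterly count) × 3e8 / state population.
    """
    mc = monthly_counts.copy()
    if (mc["count"] < 0).any():
        raise ValueError("negative death count")
    mc["quarter"] = mc["month"] // 3
    q = (
        mc.groupby(["state", "quarter", "cause_category"], as_index=False)["count"].sum()
    )
    pop = population[["state", "quarter", "population"]]
    if (pop["population"] <= 0).any():
        raise ValueError("population must be positive")
    out = q.merge(pop, on=["state", "quarter"], how="left")
    if out["population"].isna().any():
        raise ValueError("population missing for some state-quarters")
    out["rate_per_300m"] = out["count"] * (PER_POPULATION / out["population"])
    return out[["state", "quarter", "cause_category", "count", "rate_per_300m"]]
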