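"""State policy effective dates → binary state × quarter treatment panels.

A policy table has one row per (state, policy_type) with an effective year
and month, or missing values for never-adopters. Treatment is absorbing:
once a law is active it stays active through the end of the window, so each
flag column is monotone non-decreasing in time within a state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quarters import QuarterWindow

#: The six analysed opioid policies, in the order they are reported.
OPIOID_POLICIES: tuple[str, ...] = (
    "pdmp_access",
    "pdmp_mandatory",
    "prescription_limit",
    "pain_clinic",
    "good_samaritan",
    "naloxone_access",
)

#: Policies aimed at controlling the prescription-opioid supply.
SUPPLY_POLICIES: tuple[str, ...] = (
    "pdmp_access", "pdmp_mandatory", "prescription_limit", "pain_clinic",
)

#: Policies aimed at reducing harms / barriers to overdose assistance.
HARM_REDUCTION_POLICIES: tuple[str, ...] = ("good_samaritan", "naloxone_access")

#: Medicaid expansion rides along as a control indicator, not a treatment.
ALL_POLICY_TYPES: tuple[str, ...] = OPIOID_POLICIES + ("medicaid_expansion",)

POLICY_SCHEMA = ["state", "policy_type", "effective_year", "effective_month"]


def validate_policy_table(policies: pd.DataFrame) -> pd.DataFrame:
    missing = set(POLICY_SCHEMA) - set(policies.columns)
    if missing:
        raise ValueError(f"policy table missing columns: {sorted(missing)}")
    dup = policies.duplicated(["state", "policy_type"])
    if dup.any():
        raise ValueError("multiple effective dates for one (state, policy_type)")
    return policies


def build_treatment_panel(
    policies: pd.DataFrame,
    window: QuarterWindow,
    policy_types: tuple[str, ...] | None = None,
    activation: str = "enactment_quarter",
) -> pd.DataFrame:
    """Long state × quarter panel with one binary flag column per policy type.

    A law effective in any month of quarter q is active from q onward
    (``activation="enactment_quarter"``); ``"next_quarter"`` delays onset by
    one quarter. Never-adopters (missing effective date) are 0 throughout.
    """
    validate_policy_table(policies)
    if activation not in ("enactment_quarter", "next_quarter"):
        raise ValueError(f"unknown activation rule: {activation!r}")
    if policy_types is None:
        policy_types = tuple(sorted(policies["policy_type"].unique()))
    states = sorted(policies["state"].unique())
    qs = np.arange(window.n_quarters)
    panel = pd.DataFrame(
        [(s, q) for s in states for q in qs], columns=["state", "quarter"]
    )
    for p in policy_types:
        sub = policies[policies["policy_type"] == p].set_index("state")
        flags = np.zeros((len(states), window.n_quarters), dtype=np.int8)
        for i, s in enumerate(states):
            if s not in sub.index:
                continue
            row = sub.loc[s]
            y, m = row["effective_year"], row["effective_month"]
            if pd.isna(y) or pd.isna(m):
                continue
            y, m = int(y), int(m)
            if not 1 <= m <= 12:
                raise ValueError(f"effective month out of range: {s}/{p}: {m}")
            q0 = window.quarter_of_month(y, m)
            if activation == "next_quarter":
                q0 += 1
            if q0 < 0:  # effective before the window: active throughout
                q0 = 0
            if q0 < window.n_quarters:
                flags[i, q0:] = 1
        panel[p] = flags.ravel()
    return panel


def treatment_matrix(panel: pd.DataFrame, policy: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Wide (states × quarters) 0/1 matrix for one policy, plus the state index."""
    wide = panel.pivot(index="state", columns="quarter", values=policy)
    wide = wide.sort_index().sort_index(axis=1)
    T = wide.to_numpy(dtype=np.int8)
    if (np.diff(T, axis=1) < 0).any():
        raise ValueError(f"treatment for {policy!r} is not absorbing")
    return wide, T


def adoption_quarter(T: np.ndarray) -> np.ndarray:
    """First treated quarter per state, or -1 for never-treated-in-window.

    States already treated at the window start (flag 1 at quarter 0) are
    reported as adopting at 0.
    """
    treated_any = T.any(axis=1)
    first = np.where(treated_any, T.argmax(axis=1), -1)
    return first
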