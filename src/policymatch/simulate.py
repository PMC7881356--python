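"""Synthetic study inputs with known injected policy effects.

The generator emulates the four input surfaces the pipeline consumes —
patient-level pharmacy/medical claims, state × quarter covariates,
staggered policy effective dates, and record-level overdose deaths — with
user-specified ground-truth effect schedules, so that every downstream
stage (indicator engine, mortality path, matching estimator, pooling) can
be tested against known truth.

Structure injected:

* policy adoption is a per-quarter hazard process; treatment is absorbing
  (no repeal), so cumulative adoption counts only grow;
* state-quarter outcomes follow intercept + common trend + state-specific
  pre-trend slope + injected lagged effect schedule + Gaussian noise
  (the data-generating process the matching estimator assumes);
* claim streams are modulated by active supply-controlling policies (the
  any-opioid fill probability and the high-dose regimen probability move
  by the scheduled amounts), so the indicator engine can recover effects;
* heroin/synthetic overdose death rates are modulated by active
  harm-reduction policies.

Each component draws from its own RNG stream derived from the master seed,
so changing one component's parameters never perturbs another's draws.
Effect schedules give the effect at leads 0..F_max and plateau at their
last value thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import icd
from .policies import (ALL_POLICY_TYPES, HARM_REDUCTION_POLICIES,
                       OPIOID_POLICIES, SUPPLY_POLICIES)
from .quarters import QuarterWindow

_STREAMS = {"policies": 0, "outcomes": 1, "claims": 2, "deaths": 3, "covariates": 4}

ICD10_START = pd.Timestamp("2015-10-01")

_DEFAULT_DEATH_RATES = {  # baseline deaths per 300M people per quarter
    "heroin_T401": 300.0,
    "natural_T402": 500.0,
    "methadone_T403": 120.0,
    "synthetic_T404": 400.0,
    "cocaine_T405": 250.0,
    "other_T406": 150.0,
}


def schedule_value(schedule: Sequence[float], lead: int) -> float:
    """Effect at a given lead; schedules plateau at their last value."""
    s = np.asarray(schedule, dtype=float)
    if lead < 0 or len(s) == 0:
        return 0.0
    return float(s[min(lead, len(s) - 1)])


@dataclass
class SimConfig:
    """Study conditions for one synthetic replicate.

    ``true_effect_schedule`` maps policy → outcome → per-lead effects on the
    state-quarter panel outcomes (outcome units). ``claim_effect_schedule``
    maps policy → per-lead shifts of the any-opioid fill probability;
    ``high_dose_effect_schedule`` likewise for the high-dose regimen
    probability. ``death_effect_schedule`` maps policy → cause category →
    per-lead shifts of the quarterly death rate per 300M people.
    """

    n_states: int = 50
    n_quarters: int = 48
    start_year: int = 2007
    patients_per_state: int = 200
    adoption_hazard: float = 0.02
    policy_types: tuple[str, ...] = ALL_POLICY_TYPES
    outcomes: Mapping[str, float] = field(default_factory=lambda: {"outcome": 0.0})
    true_effect_schedule: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=dict
    )
    state_intercept_sd: float = 1.0
    common_trend: float = 0.0
    pre_trend_slope_sd: float = 0.0
    noise_sd: float = 1.0
    # claim-stream parameters
    base_opioid_rate: float = 0.12       # P(patient fills any opioid | quarter)
    high_dose_rate: float = 0.02         # P(high-dose regimen | user-quarter)
    shopper_rate: float = 0.002          # lifetime P(patient is a doctor-shopper)
    mat_rate: float = 0.01               # P(MAT fill | user-quarter)
    methadone_rate: float = 0.002        # P(methadone fill | user-quarter)
    oud_dx_rate: float = 0.005           # P(OUD/overdose dx | user-quarter)
    cancer_rate: float = 0.02            # lifetime P(cancer/palliative dx)
    claim_effect_schedule: Mapping[str, Sequence[float]] = field(default_factory=dict)
    high_dose_effect_schedule: Mapping[str, Sequence[float]] = field(default_factory=dict)
    # mortality parameters
    base_death_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEATH_RATES)
    )
    death_effect_schedule: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=dict
    )
    polysubstance_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quarters < 2:
            raise ValueError("n_quarters must be >= 2")
        if not 0.0 <= self.adoption_hazard <= 1.0:
            raise ValueError("adoption_hazard must be in [0, 1]")
        for name in ("state_intercept_sd", "pre_trend_slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.patients_per_state < 0 or self.n_states < 1:
            raise ValueError("counts must be nonnegative")
        for sched_map in (self.true_effect_schedule, self.death_effect_schedule):
            for p, per_out in sched_map.items():
                for o, s in per_out.items():
                    if len(np.atleast_1d(s)) == 0:
                        raise ValueError(f"empty effect schedule for ({p}, {o})")

    @property
    def window(self) -> QuarterWindow:
        return QuarterWindow(self.start_year, self.n_quarters)

    @property
    def states(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_states + 1)]

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[component]])


@dataclass
class SyntheticBundle:
    """All generated inputs plus the injected ground truth."""

    claims: pd.DataFrame
    diagnoses: pd.DataFrame
    roster: pd.DataFrame
    policies: pd.DataFrame
    covariates: pd.DataFrame
    deaths: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------

def simulate_policy_adoption(cfg: SimConfig) -> pd.DataFrame:
    """Staggered adoption dates: per-quarter hazard, absorbing once adopted.

    Returns the long policy table (state, policy_type, effective_year,
    effective_month) with missing dates for never-adopters. The effective
    month is uniform within the adoption quarter.
    """
    rng = cfg.rng("policies")
    rows = []
    for s in cfg.states:
        for p in cfg.policy_types:
            u = rng.random(cfg.n_quarters)
            month_u = rng.integers(0, 3)
            hit = np.flatnonzero(u < cfg.adoption_hazard)
            if len(hit) == 0:
                rows.append((s, p, np.nan, np.nan))
                continue
            q = int(hit[0])
            year = cfg.start_year + q // 4
            month = 3 * (q % 4) + 1 + int(month_u)
            rows.append((s, p, year, month))
    return pd.DataFrame(
        rows, columns=["state", "policy_type", "effective_year", "effective_month"]
    )


def _adoption_quarters(cfg: SimConfig, policies: pd.DataFrame) -> dict[str, np.ndarray]:
    """policy → per-state adoption quarter index (-1 = never)."""
    w = cfg.window
    out = {}
    idx = {s: i for i, s in enumerate(cfg.states)}
    for p in policies["policy_type"].unique():
        a = np.full(cfg.n_states, -1, dtype=int)
        sub = policies[policies["policy_type"] == p]
        for rec in sub.itertuples(index=False):
            if pd.isna(rec.effective_year) or rec.state not in idx:
                continue
            a[idx[rec.state]] = w.quarter_of_month(rec.effective_year, rec.effective_month)
        out[p] = a
    return out


def _effect_surface(
    cfg: SimConfig,
    adoption: dict[str, np.ndarray],
    schedules: Mapping[str, Sequence[float]],
) -> np.ndarray:
    """(S, Q) cumulative injected effect from all scheduled policies."""
    S, Q = cfg.n_states, cfg.n_quarters
    eff = np.zeros((S, Q))
    for p, sched in schedules.items():
        a = adoption.get(p)
        if a is None:
            continue
        for s in range(S):
            if a[s] < 0 or a[s] >= Q:
                continue
            leads = np.arange(Q - a[s])
            vals = np.asarray(sched, dtype=float)
            eff[s, a[s]:] += vals[np.minimum(leads, len(vals) - 1)]
    return eff


# ---------------------------------------------------------------------------
# state-quarter outcomes
# ---------------------------------------------------------------------------

def simulate_state_outcomes(cfg: SimConfig, policies: pd.DataFrame) -> pd.DataFrame:
    """Long state × quarter panel with one column per configured outcome.

    outcome(s, q) = baseline + intercept_s + common trend · q + slope_s · q
    + Σ_adopted schedule[q − adoption_q] + N(0, noise_sd²). The injected
    effect begins at lead 0 (the adoption quarter itself).
    """
    missing = set(policies["state"].unique()) - set(cfg.states)
    if missing:
        raise ValueError(f"policy table has unknown states: {sorted(missing)}")
    rng = cfg.rng("outcomes")
    S, Q = cfg.n_states, cfg.n_quarters
    adoption = _adoption_quarters(cfg, policies)
    q = np.arange(Q)
    out = pd.DataFrame(
        [(s, qq) for s in cfg.states for qq in q], columns=["state", "quarter"]
    )
    for name, baseline in cfg.outcomes.items():
        intercepts = rng.normal(0.0, cfg.state_intercept_sd, S)
        slopes = rng.normal(0.0, cfg.pre_trend_slope_sd, S)
        noise = rng.normal(0.0, cfg.noise_sd, (S, Q))
        sched = {
            p: per_out[name]
            for p, per_out in cfg.true_effect_schedule.items()
            if name in per_out
        }
        eff = _effect_surface(cfg, adoption, sched)
        Y = (
            baseline
            + intercepts[:, None]
            + cfg.common_trend * q[None, :]
            + slopes[:, None] * q[None, :]
            + eff
            + noise
        )
        out[name] = Y.ravel()
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(cfg: SimConfig, policies: pd.DataFrame) -> pd.DataFrame:
    """State × quarter confounder panel (demographics, economy, population)."""
    rng = cfg.rng("covariates")
    S, Q = cfg.n_states, cfg.n_quarters
    adoption = _adoption_quarters(cfg, policies)
    medicaid = adoption.get("medicaid_expansion", np.full(S, -1))
    female = np.clip(rng.normal(0.51, 0.01, S), 0.45, 0.55)
    age = rng.dirichlet([50, 35, 15], S)  # <40, 40-60, >60
    race = rng.dirichlet([60, 12, 5, 15, 8], S)  # white, black, asian, hispanic, other
    unemp0 = np.clip(rng.normal(0.06, 0.015, S), 0.02, 0.12)
    pov0 = np.clip(rng.normal(0.13, 0.03, S), 0.05, 0.25)
    pop = np.exp(rng.normal(np.log(4e6), 0.8, S)).astype(int)
    rows = []
    for i, s in enumerate(cfg.states):
        drift = 0.002 * np.sin(2 * np.pi * np.arange(Q) / 16 + i)
        for qq in range(Q):
            rows.append(
                (
                    s, qq, female[i],
                    age[i, 0], age[i, 1], age[i, 2],
                    race[i, 0], race[i, 1], race[i, 2], race[i, 3], race[i, 4],
                    float(np.clip(unemp0[i] + drift[qq], 0.01, 0.2)),
                    float(np.clip(pov0[i] + drift[qq], 0.02, 0.3)),
                    int(pop[i] * (1 + 0.001 * qq)),
                    int(0 <= medicaid[i] <= qq),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "state", "quarter", "female", "age_lt40", "age_40_60", "age_gt60",
            "white", "black", "asian", "hispanic", "other_race",
            "unemployed", "poverty", "population", "medicaid_expansion",
        ],
    )


# ---------------------------------------------------------------------------
# claims + diagnoses
# ---------------------------------------------------------------------------

def _dx_code(category: str, date: pd.Timestamp) -> tuple[str, int]:
    v10 = date >= ICD10_START
    codes = {
        "oud": ("F11.20", "3040"),
        "overdose": ("T40.2X1A", "9650"),
        "cancer": ("C50.9", "174"),
        "palliative": ("Z51.5", "V667"),
    }
    ten, nine = codes[category]
    return (ten, 10) if v10 else (nine, 9)


def simulate_claims(cfg: SimConfig, policies: pd.DataFrame) -> SyntheticBundle:
    """Full synthetic bundle: claims, diagnoses, covariates, deaths, truth.

    Per state-quarter the any-opioid fill probability is
    base_opioid_rate + Σ active supply-policy claim schedules (clipped to
    [0.001, 0.95]); the realised target is stored in ``truth["targets"]``.
    Planted doctor-shoppers fill from ≥4 prescribers and ≥4 pharmacies
    inside one 90-day span; planted high-dose user-quarters exceed 90 daily
    MME; a share of user-quarters receive MAT or methadone fills and
    OUD/overdose diagnoses; a share of patients carry cancer/palliative
    diagnoses and are expected to be excluded downstream.
    """
    rng = cfg.rng("claims")
    w = cfg.window
    adoption = _adoption_quarters(cfg, policies)
    qb = w.quarter_day_bounds()

    p_any = np.clip(
        cfg.base_opioid_rate
        + _effect_surface(cfg, adoption, dict(cfg.claim_effect_schedule)),
        0.001, 0.95,
    )
    p_hd = np.clip(
        cfg.high_dose_rate
        + _effect_surface(cfg, adoption, dict(cfg.high_dose_effect_schedule)),
        0.0, 1.0,
    )

    claims_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    roster_rows: list[tuple] = []

    def add_claim(pid, state, day, ds, daily_dose, cls, doc, pharm):
        upd, factor = 3.0, 1.5
        strength = daily_dose / (upd * factor) if cls == "opioid" else 1.0
        date = w.start_date + pd.Timedelta(days=int(day))
        claims_rows.append(
            (pid, state, date, int(ds), upd * ds, strength, factor, cls, doc, pharm)
        )

    for si, state in enumerate(cfg.states):
        n = cfg.patients_per_state
        pids = [f"{state}-P{i:04d}" for i in range(n)]
        roster_rows.extend((state, pid) for pid in pids)
        if n == 0:
            continue
        docs = [f"{state}-D{i:03d}" for i in range(max(8, n // 10))]
        pharms = [f"{state}-F{i:03d}" for i in range(max(8, n // 20))]
        home_doc = rng.integers(0, len(docs), n)
        home_pharm = rng.integers(0, len(pharms), n)
        cancer = rng.random(n) < cfg.cancer_rate
        shopper = rng.random(n) < cfg.shopper_rate
        shopper_q = rng.integers(1, cfg.n_quarters, n)
        user = rng.random((n, cfg.n_quarters)) < p_any[si][None, :]
        for i in range(n):
            if cancer[i]:
                d0 = int(rng.integers(0, w.n_days))
                date = w.start_date + pd.Timedelta(days=d0)
                cat = "cancer" if rng.random() < 0.75 else "palliative"
                code, ver = _dx_code(cat, date)
                dx_rows.append((pids[i], date, code, ver))
            uq = np.flatnonzero(user[i])
            for q in uq:
                lo, hi = qb[q]
                day = int(rng.integers(lo, hi + 1))
                ds = int(rng.choice([7, 14, 30]))
                dose = float(np.clip(rng.normal(40, 15), 10, 85))
                doc = docs[home_doc[i]] if rng.random() < 0.8 else docs[int(rng.integers(0, len(docs)))]
                ph = pharms[home_pharm[i]] if rng.random() < 0.8 else pharms[int(rng.integers(0, len(pharms)))]
                add_claim(pids[i], state, day, ds, dose, "opioid", doc, ph)
                if rng.random() < 0.25:  # refill, possibly overlapping
                    day2 = min(day + int(rng.integers(5, ds + 10)), w.n_days - 1)
                    add_claim(pids[i], state, day2, ds,
                              float(np.clip(rng.normal(40, 15), 10, 85)),
                              "opioid", doc, ph)
                if rng.random() < p_hd[si, q]:
                    add_claim(pids[i], state, day, 30,
                              float(rng.uniform(95, 150)), "opioid", doc, ph)
                if rng.random() < cfg.mat_rate:
                    add_claim(pids[i], state, day, 30, 0.0, "mat", doc, ph)
                if rng.random() < cfg.methadone_rate:
                    add_claim(pids[i], state, day, 30, 0.0, "methadone", doc, ph)
                if rng.random() < cfg.oud_dx_rate:
                    date = w.start_date + pd.Timedelta(days=day)
                    cat = "oud" if rng.random() < 0.8 else "overdose"
                    code, ver = _dx_code(cat, date)
                    dx_rows.append((pids[i], date, code, ver))
            if shopper[i]:
                lo, hi = qb[shopper_q[i]]
                base_day = int(rng.integers(lo, min(hi, w.n_days - 90) + 1)) if lo < w.n_days - 90 else int(lo)
                picks_d = rng.choice(len(docs), 4, replace=False)
                picks_f = rng.choice(len(pharms), 4, replace=False)
                for k in range(4):
                    add_claim(pids[i], state, base_day + 20 * k, 7,
                              float(np.clip(rng.normal(40, 15), 10, 85)),
                              "opioid", docs[picks_d[k]], pharms[picks_f[k]])

    claims = pd.DataFrame(
        claims_rows,
        columns=[
            "patient_id", "state", "fill_date", "days_supply", "quantity",
            "strength_per_unit", "mme_factor", "drug_class",
            "prescriber_id", "pharmacy_id",
        ],
    )
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "date", "code", "icd_version"]
    )
    roster = pd.DataFrame(roster_rows, columns=["state", "patient_id"])
    covariates = simulate_covariates(cfg, policies)
    deaths = simulate_deaths(cfg, policies, covariates)

    targets = pd.DataFrame(
        [
            (s, q, p_any[i, q], p_hd[i, q])
            for i, s in enumerate(cfg.states)
            for q in range(cfg.n_quarters)
        ],
        columns=["state", "quarter", "target_p_any_opioid", "target_p_high_dose"],
    )
    truth = {
        "true_effect_schedule": _jsonable(cfg.true_effect_schedule),
        "claim_effect_schedule": _jsonable({"_": dict(cfg.claim_effect_schedule)})["_"],
        "high_dose_effect_schedule": _jsonable({"_": dict(cfg.high_dose_effect_schedule)})["_"],
        "death_effect_schedule": _jsonable(cfg.death_effect_schedule),
        "targets": targets,
    }
    return SyntheticBundle(claims, diagnoses, roster, policies, covariates, deaths, truth)


# ---------------------------------------------------------------------------
# deaths
# ---------------------------------------------------------------------------

def simulate_deaths(
    cfg: SimConfig, policies: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Record-level overdose deaths (state, year, month, codes).

    Monthly per-cause counts are Poisson with mean
    (base rate + Σ active policy schedules) × population / 3e8 / 3.
    Each record gets an underlying overdose code and the cause's T-code;
    a share of records carry a second T-code (polysubstance).
    """
    rng = cfg.rng("deaths")
    w = cfg.window
    adoption = _adoption_quarters(cfg, policies)
    pop = (
        covariates.drop_duplicates(["state", "quarter"])
        .set_index(["state", "quarter"])["population"]
    )
    underlying_codes = sorted(icd.OVERDOSE_UNDERLYING)
    t_by_cause = {v: k for k, v in icd.T_CODE_CATEGORIES.items()}
    causes = list(cfg.base_death_rates)
    rate_surface = {
        c: np.clip(
            cfg.base_death_rates[c]
            + _effect_surface(
                cfg, adoption,
                {p: per_out[c] for p, per_out in cfg.death_effect_schedule.items()
                 if c in per_out},
            ),
            0.0, None,
        )
        for c in causes
    }
    rows = []
    for si, s in enumerate(cfg.states):
        for m in range(w.n_months):
            q = m // 3
            p = pop.loc[(s, q)]
            year, month = cfg.start_year + m // 12, m % 12 + 1
            for c in causes:
                lam = rate_surface[c][si, q] * p / 3e8 / 3.0
                k = rng.poisson(lam)
                for _ in range(k):
                    und = underlying_codes[int(rng.integers(0, len(underlying_codes)))]
                    contrib = [t_by_cause[c]]
                    if rng.random() < cfg.polysubstance_rate:
                        extra = causes[int(rng.integers(0, len(causes)))]
                        if extra != c:
                            contrib.append(t_by_cause[extra])
                    rows.append((s, year, month, und, ";".join(contrib)))
    return pd.DataFrame(
        rows, columns=["state", "year", "month", "underlying_cause", "contributing_codes"]
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _jsonable(sched_map) -> dict:
    return {
        p: {o: list(np.asarray(s, dtype=float)) for o, s in per.items()}
        for p, per in sched_map.items()
    }


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as delimited text files plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("claims", "diagnoses", "roster", "policies", "covariates", "deaths"):
        path = outdir / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    truth = {k: v for k, v in bundle.truth.items() if k != "targets"}
    tpath = outdir / "truth.json"
    tpath.write_text(json.dumps(truth, indent=2))
    paths["truth"] = tpath
    gpath = outdir / "targets.csv"
    bundle.truth["targets"].to_csv(gpath, index=False)
    paths["targets"] = gpath
    return paths
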