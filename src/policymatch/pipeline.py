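"""File-driven pipeline: simulate → indicators → mortality → panel → match → pool.

Each stage reads and writes delimited text tables in a run directory, so
any stage can be re-run from its input files alone. ``run_pipeline`` chains
them, writes a JSON manifest recording every configuration value, and (for
synthetic runs) a recovery report comparing pooled effect signs with the
injected truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .claims import IndicatorConfig, compute_indicators
from .matching import DEFAULT_F_MAX, DEFAULT_LAG, bootstrap_ci
from .meta import classify_effect, pool_random_effects, pool_with_draws
from .mortality import classify_death_records, deaths_to_rate
from .policies import OPIOID_POLICIES, build_treatment_panel, treatment_matrix
from .quarters import QuarterWindow
from .simulate import SimConfig, simulate_claims, simulate_policy_adoption, write_bundle

logger = logging.getLogger(__name__)

INDICATOR_OUTCOMES = (
    "p_any_opioid", "p_oud_overdose", "p_mme90",
    "p_doctor_shopping", "p_overlap", "p_mat",
)
MORTALITY_OUTCOMES = (
    "all_drug", "heroin_T401", "natural_T402", "methadone_T403",
    "synthetic_T404", "cocaine_T405", "other_T406",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML/JSON."""

    outdir: str = "run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    indicators: dict = field(default_factory=dict)
    matching: dict = field(default_factory=dict)
    pooling: dict = field(default_factory=dict)
    policies: tuple = OPIOID_POLICIES
    outcomes: tuple = INDICATOR_OUTCOMES + MORTALITY_OUTCOMES

    def __post_init__(self) -> None:
        known = set(INDICATOR_OUTCOMES) | set(MORTALITY_OUTCOMES)
        for o in self.outcomes:
            if o not in known:
                raise ValueError(f"unknown outcome name: {o!r}")
        from .policies import ALL_POLICY_TYPES
        for p in self.policies:
            if p not in ALL_POLICY_TYPES:
                raise ValueError(f"unknown policy name: {p!r}")

    @property
    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    @property
    def indicator_config(self) -> IndicatorConfig:
        return IndicatorConfig(**self.indicators)


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    for key in ("policies", "outcomes"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _require(df: pd.DataFrame, cols: list[str], table: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing required column(s) {missing}")
    return df


def _read(path: Path, cols: list[str], parse_dates: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=parse_dates or [])
    return _require(df, cols, path.name)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    sim = cfg.sim_config
    policies = simulate_policy_adoption(sim)
    bundle = simulate_claims(sim, policies)
    write_bundle(bundle, outdir)


def stage_indicators(cfg: RunConfig, outdir: Path) -> None:
    sim = cfg.sim_config
    claims = _read(outdir / "claims.csv", [
        "patient_id", "state", "fill_date", "days_supply", "quantity",
        "strength_per_unit", "mme_factor", "drug_class",
        "prescriber_id", "pharmacy_id"], ["fill_date"])
    diagnoses = _read(outdir / "diagnoses.csv",
                      ["patient_id", "date", "code", "icd_version"], ["date"])
    roster = _read(outdir / "roster.csv", ["state", "patient_id"])
    table = compute_indicators(claims, diagnoses, roster, sim.window,
                               cfg.indicator_config)
    table.to_csv(outdir / "indicators.csv", index=False)


def stage_mortality(cfg: RunConfig, outdir: Path) -> None:
    sim = cfg.sim_config
    deaths = _read(outdir / "deaths.csv",
                   ["state", "year", "month", "underlying_cause", "contributing_codes"])
    covariates = _read(outdir / "covariates.csv", ["state", "quarter", "population"])
    monthly = classify_death_records(deaths, sim.window)
    monthly.to_csv(outdir / "monthly_counts.csv", index=False)
    rates = deaths_to_rate(monthly, covariates, sim.window)
    rates.to_csv(outdir / "mortality_panel.csv", index=False)


def stage_panel(cfg: RunConfig, outdir: Path) -> None:
    sim = cfg.sim_config
    policies = _read(outdir / "policies.csv",
                     ["state", "policy_type", "effective_year", "effective_month"])
    panel = build_treatment_panel(policies, sim.window)
    panel.to_csv(outdir / "treatment_panel.csv", index=False)


def _outcome_wide(outcome: str, outdir: Path) -> pd.DataFrame:
    if outcome in INDICATOR_OUTCOMES:
        t = _read(outdir / "indicators.csv", ["state", "quarter", outcome])
        return t.pivot(index="state", columns="quarter", values=outcome)
    t = _read(outdir / "mortality_panel.csv",
              ["state", "quarter", "cause_category", "rate_per_300m"])
    t = t[t["cause_category"] == outcome]
    return t.pivot(index="state", columns="quarter", values="rate_per_300m")


def stage_match(cfg: RunConfig, outdir: Path) -> None:
    m = cfg.matching
    panel = _read(outdir / "treatment_panel.csv", ["state", "quarter"])
    covariates = None
    if m.get("refinement", "cbps") not in (None, "none", "uniform"):
        covariates = _read(outdir / "covariates.csv", ["state", "quarter"])
    rows = []
    draw_frames = []
    rng = np.random.default_rng([cfg.seed, 97])
    f_max = m.get("f_max", DEFAULT_F_MAX)
    for policy in cfg.policies:
        _require(panel, [policy], "treatment_panel.csv")
        wide_t, _ = treatment_matrix(panel, policy)
        for outcome in cfg.outcomes:
            wide_y = _outcome_wide(outcome, outdir).reindex(wide_t.index)
            ests, draws = bootstrap_ci(
                wide_t, wide_y,
                L=m.get("L", DEFAULT_LAG),
                f_max=f_max,
                B=m.get("B", 500),
                alpha=m.get("alpha", 0.05),
                seed=rng,
                covariates=covariates,
                method=m.get("refinement", "cbps"),
                j=m.get("J", 3),
                condition_on_pre_outcomes=m.get("condition_on_pre_outcomes", True),
                policy_type=policy, outcome=outcome,
                return_draws=True,
            )
            rows.extend(dataclasses.asdict(e) for e in ests)
            dd = pd.DataFrame(draws, columns=[f"lead{f}" for f in range(f_max + 1)])
            dd.insert(0, "rep", np.arange(len(dd)))
            dd.insert(0, "outcome", outcome)
            dd.insert(0, "policy", policy)
            draw_frames.append(dd)
    pd.DataFrame(rows).rename(columns={"policy_type": "policy"}).to_csv(
        outdir / "att_estimates.csv", index=False
    )
    pd.concat(draw_frames, ignore_index=True).to_csv(
        outdir / "att_draws.csv", index=False, float_format="%.6g"
    )


def stage_pool(cfg: RunConfig, outdir: Path) -> None:
    att = _read(outdir / "att_estimates.csv",
                ["policy", "outcome", "lead", "estimate", "se",
                 "ci_low", "ci_high", "n_sets"])
    method = cfg.pooling.get("method", "reml")
    # "bootstrap" CIs (default) pool each block-bootstrap replicate of the
    # lead profile, respecting between-lead dependence; "wald" uses the
    # independent-leads random-effects interval.
    ci_kind = cfg.pooling.get("ci", "bootstrap")
    draws_path = outdir / "att_draws.csv"
    draws_all = pd.read_csv(draws_path) if draws_path.exists() else None
    if ci_kind == "bootstrap" and draws_all is None:
        raise ValueError("pooling.ci='bootstrap' requires att_draws.csv from the match stage")
    rows = []
    for (policy, outcome), sub in att.groupby(["policy", "outcome"]):
        sub = sub.sort_values("lead")
        usable = sub[np.isfinite(sub["estimate"]) & (sub["se"] > 0)]
        if len(usable) < 2:
            logger.warning("skipping pooling for (%s, %s): %d usable leads",
                           policy, outcome, len(usable))
            continue
        if ci_kind == "bootstrap":
            d = draws_all[(draws_all["policy"] == policy)
                          & (draws_all["outcome"] == outcome)]
            lead_cols = [f"lead{f}" for f in sub["lead"]]
            try:
                pooled = pool_with_draws(
                    sub["estimate"], sub["se"], d[lead_cols].to_numpy(float),
                    policy, outcome, method=method,
                )
            except ValueError as exc:
                logger.warning("bootstrap pooling failed for (%s, %s): %s; "
                               "falling back to Wald CI", policy, outcome, exc)
                pooled = pool_random_effects(
                    usable["estimate"], usable["se"], policy, outcome, method=method
                )
        else:
            pooled = pool_random_effects(
                usable["estimate"], usable["se"], policy, outcome, method=method
            )
        rows.append({
            "policy": policy, "outcome": outcome,
            "mean_effect": pooled.mean_effect,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
            "se": pooled.se, "tau2": pooled.tau2, "k": pooled.k,
            "sign": pooled.sign, "significant": pooled.significant,
            "label": classify_effect(pooled),
        })
    pd.DataFrame(rows).to_csv(outdir / "pooled_effects.csv", index=False)


def _recovery_report(outdir: Path) -> None:
    truth_path = outdir / "truth.json"
    pooled_path = outdir / "pooled_effects.csv"
    if not (truth_path.exists() and pooled_path.exists()):
        return
    truth = json.loads(truth_path.read_text())
    pooled = pd.read_csv(pooled_path)
    rows = []
    for kind in ("true_effect_schedule", "death_effect_schedule"):
        for policy, per_out in truth.get(kind, {}).items():
            for outcome, sched in per_out.items():
                mean_true = float(np.mean(sched))
                hit = pooled[(pooled["policy"] == policy) & (pooled["outcome"] == outcome)]
                if len(hit):
                    est = float(hit["mean_effect"].iloc[0])
                    rows.append({
                        "policy": policy, "outcome": outcome,
                        "mean_true_effect": mean_true, "pooled_estimate": est,
                        "sign_recovered": bool(np.sign(est) == np.sign(mean_true)),
                    })
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "recovery_report.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "indicators": stage_indicators,
    "mortality": stage_mortality,
    "panel": stage_panel,
    "match": stage_match,
    "pool": stage_pool,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the configured stages (all of them by default); returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in stages or list(STAGES):
        logger.info("stage: %s", name)
        STAGES[name](cfg, outdir)
    _recovery_report(outdir)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "outdir": str(cfg.outdir),
            "sim": dict(cfg.sim),
            "indicators": dict(cfg.indicators),
            "matching": dict(cfg.matching),
            "pooling": dict(cfg.pooling),
            "policies": list(cfg.policies),
            "outcomes": list(cfg.outcomes),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
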