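"""Random-effects pooling of lead-specific effect estimates.

For one (policy, outcome) pair the matching stage produces up to 13
lead-specific ATT estimates y_f with standard errors se_f (leads 0..12).
These are pooled with the standard random-effects model

    y_f = mu + u_f + e_f,   u_f ~ N(0, tau^2),   e_f ~ N(0, se_f^2),

estimated by REML (default) or DerSimonian–Laird, with inverse-variance
weights w_f = 1/(se_f^2 + tau^2) and a Wald 95% CI for mu. An association
is *negative* if the pooled mean is negative (ties broken to positive) and
*significant* if the CI excludes zero — the rule used to shade the policy ×
outcome summary grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects summary of lead-specific estimates for one (policy, outcome)."""

    policy_type: str
    outcome: str
    mean_effect: float
    ci_low: float
    ci_high: float
    se: float
    tau2: float
    k: int
    method: str

    @property
    def sign(self) -> str:
        return "negative" if self.mean_effect < 0 else "positive"

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _weighted_mean(y: np.ndarray, v: np.ndarray, tau2: float) -> tuple[float, float]:
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return mu, se


def tau2_dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments between-study variance: tau2 = max(0, (Q-(k-1))/C)."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - 1)) / c)


def _neg_restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    """REML between-study variance by bounded scalar optimisation."""
    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        _neg_restricted_loglik, args=(y, v), bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    # the bounded optimiser cannot land exactly on 0; snap when the boundary wins
    if _neg_restricted_loglik(0.0, y, v) <= res.fun:
        tau2 = 0.0
    return tau2


def pool_random_effects(
    estimates,
    ses,
    policy_type: str = "",
    outcome: str = "",
    method: str = "reml",
    alpha: float = 0.05,
) -> PooledEffect:
    """Pool lead-specific estimates into one mean effect with a Wald CI.

    Missing leads (NaN estimate or SE) are dropped, reducing k. All-zero SEs
    are degenerate: the simple mean with a zero-width CI is returned with a
    warning.
    """
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    keep = np.isfinite(y) & np.isfinite(s)
    y, s = y[keep], s[keep]
    if len(y) == 0:
        raise ValueError("no usable estimates to pool")
    if np.all(s == 0):
        warnings.warn("all standard errors are zero; returning the simple mean")
        mu = float(np.mean(y))
        return PooledEffect(policy_type, outcome, mu, mu, mu, 0.0, 0.0, len(y), method)
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    if len(y) == 1:
        mu, se = float(y[0]), float(s[0])
        tau2 = 0.0
    else:
        v = s**2
        if method == "reml":
            tau2 = tau2_reml(y, v)
        elif method in ("dl", "dersimonian-laird"):
            tau2 = tau2_dersimonian_laird(y, v)
        else:
            raise ValueError(f"unknown tau2 method: {method!r}")
        mu, se = _weighted_mean(y, v, tau2)
    z = stats.norm.ppf(1 - alpha / 2)
    return PooledEffect(
        policy_type, outcome, mu, mu - z * se, mu + z * se, se, tau2, len(y), method
    )


def pool_with_draws(
    estimates,
    ses,
    draws: np.ndarray,
    policy_type: str = "",
    outcome: str = "",
    method: str = "reml",
    alpha: float = 0.05,
) -> PooledEffect:
    """Random-effects pooling with a bootstrap (dependence-aware) CI.

    Lead-specific estimates from one panel share matched sets and baseline
    outcomes, so their sampling errors are correlated and the Wald CI of
    :func:`pool_random_effects` understates pooled uncertainty. Here tau² and
    the inverse-variance weights come from the random-effects model as usual,
    but the CI is the percentile interval of the weighted mean applied to
    each block-bootstrap replicate of the lead profile (``draws``: B × leads),
    which inherits the between-state resampling dependence structure.
    """
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    keep = np.isfinite(y) & np.isfinite(s) & (s > 0)
    if keep.sum() < 2:
        raise ValueError("need >=2 usable lead estimates")
    yk, sk = y[keep], s[keep]
    v = sk**2
    tau2 = tau2_reml(yk, v) if method == "reml" else tau2_dersimonian_laird(yk, v)
    w_full = np.zeros(len(y))
    w_full[keep] = 1.0 / (v + tau2)
    mu = float(np.sum(w_full[keep] * yk) / np.sum(w_full[keep]))

    D = np.asarray(draws, dtype=float)
    W = np.where(np.isfinite(D), w_full[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_draws = np.nansum(W * np.nan_to_num(D), axis=1) / W.sum(axis=1)
    pooled_draws = pooled_draws[np.isfinite(pooled_draws)]
    if len(pooled_draws) < 100:
        raise ValueError("too few usable bootstrap draws for a percentile CI")
    lo = float(np.percentile(pooled_draws, 100 * alpha / 2))
    hi = float(np.percentile(pooled_draws, 100 * (1 - alpha / 2)))
    se = float(np.std(pooled_draws, ddof=1))
    return PooledEffect(policy_type, outcome, mu, lo, hi, se, float(tau2),
                        int(keep.sum()), f"{method}+bootstrap")


def classify_effect(pooled: PooledEffect) -> str:
    """Shading label: {significant-negative, negative, significant-positive, positive}."""
    label = pooled.sign
    return f"significant-{label}" if pooled.significant else label
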