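"""Panel-matching difference-in-differences estimator for staggered policy adoption.

The estimator follows the panel-matching recipe for absorbing binary
treatments on a state × quarter panel:

1. every (state, t) where the treatment flag switches 0→1 is a treated
   event; its control pool is the states whose treatment history matches the
   treated state's over the L pre-treatment quarters [t−L, t−1] and that
   remain untreated at t (with an absorbing treatment this means "untreated
   through t");
2. control weights within each matched set are refined so that weighted
   control means of covariates and pre-treatment outcome lags balance the
   treated unit (covariate-balancing propensity scores by default, with
   entropy/IPW/nearest-neighbour/uniform alternatives);
3. the lead-F effect is the average over matched sets of the
   difference-in-differences contrast
   [Y_tr(t+F) − Y_tr(t−1)] − Σ_c w_c [Y_c(t+F) − Y_c(t−1)];
4. uncertainty comes from a block bootstrap that resamples whole state
   trajectories and recomputes matching and estimation per replicate
   (percentile intervals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)

DEFAULT_F_MAX = 12  # effects tracked for up to 3 years of quarterly leads
DEFAULT_LAG = 4     # one year of identical pre-treatment history


@dataclass
class MatchedSet:
    """One treated (state, t) event with its weighted control states."""

    treated_state: str
    t: int
    controls: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.controls) != len(self.weights):
            raise ValueError("one weight per control state required")
        if len(self.weights) and (
            (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-8
        ):
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def empty(self) -> bool:
        return len(self.controls) == 0


@dataclass(frozen=True)
class ATTEstimate:
    """Average effect on adopting states at lead F, in outcome units."""

    policy_type: str
    outcome: str
    lead: int
    estimate: float
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_sets: int = 0


# ---------------------------------------------------------------------------
# array engine (used directly by the bootstrap; public API wraps it)
# ---------------------------------------------------------------------------

def _first_adoption(T: np.ndarray) -> np.ndarray:
    return np.where(T.any(axis=1), T.argmax(axis=1), -1)


def _sets_array(T: np.ndarray, L: int) -> list[tuple[int, int, np.ndarray]]:
    """Matched sets as (treated_idx, t, control_idx[]) triples; empty sets kept."""
    if L < 1:
        raise ValueError("lag L must be >= 1")
    S, Q = T.shape
    adopt = _first_adoption(T)
    # cumulative sums let "all zero over [t-L, t]" be checked in O(1)
    C = np.c_[np.zeros((S, 1), dtype=int), np.cumsum(T, axis=1)]
    out = []
    for s in range(S):
        t = adopt[s]
        if t < 0:
            continue
        if t < L:
            logger.info("treated event (unit %d, t=%d) skipped: lag %d exceeds pre-period", s, t, L)
            continue
        window_sums = C[:, t + 1] - C[:, t - L]  # treated quarters in [t-L, t]
        ctrl = np.flatnonzero((window_sums == 0) & (np.arange(S) != s))
        out.append((s, t, ctrl))
    return out


def _att_profile_array(
    sets: list[tuple[int, int, np.ndarray, np.ndarray]],
    Y: np.ndarray,
    f_max: int,
    adopt: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-set DiD at each lead 0..f_max; NaN where no set contributes.

    ``adopt`` gives each unit's first treated quarter (-1 = never). At lead F
    a control must still be untreated at t+F; contaminated controls are
    dropped and the remaining weights renormalised, so the contrast never
    mixes in another unit's own treatment response. A set with no clean
    controls left is dropped at that lead only.
    """
    Q = Y.shape[1]
    sums = np.zeros(f_max + 1)
    n = np.zeros(f_max + 1, dtype=int)
    for tr, t, ctrl, w in sets:
        if len(ctrl) == 0:
            continue
        top = min(f_max, Q - 1 - t)
        if top < 0:
            continue
        d_tr = Y[tr, t : t + top + 1] - Y[tr, t - 1]
        d_c_mat = Y[ctrl, t : t + top + 1] - Y[ctrl, t - 1][:, None]
        if adopt is not None:
            a = adopt[ctrl]
            clean = (a < 0)[:, None] | (a[:, None] > t + np.arange(top + 1)[None, :])
        else:
            clean = np.ones((len(ctrl), top + 1), dtype=bool)
        W = np.where(clean & np.isfinite(d_c_mat), w[:, None], 0.0)
        wsum = W.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_c = np.einsum("cf,cf->f", W, np.nan_to_num(d_c_mat)) / wsum
        valid = np.isfinite(d_tr) & (wsum > 0)
        sums[: top + 1][valid] += (d_tr - d_c)[valid]
        n[: top + 1][valid] += 1
    with np.errstate(invalid="ignore"):
        est = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return est, n


def _uniform(sets):
    return [
        (s, t, c, np.full(len(c), 1.0 / len(c)) if len(c) else np.empty(0))
        for s, t, c in sets
    ]


# ---------------------------------------------------------------------------
# refinement weights
# ---------------------------------------------------------------------------

def entropy_weights(x_treated: np.ndarray, X_controls: np.ndarray) -> np.ndarray:
    """Minimum-KL weights solving the within-set balance moments exactly.

    Solves min Σ w log w subject to Σ w = 1 and Σ w x_c = x_treated via the
    convex dual; when the treated point lies outside the convex hull of the
    controls no solution exists and a ValueError is raised.
    """
    D = X_controls - x_treated  # (n, p)
    n, p = D.shape

    def dual(lam):
        return logsumexp(D @ lam)

    def grad(lam):
        z = D @ lam
        w = np.exp(z - logsumexp(z))
        return w @ D

    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(dual, np.zeros(p), jac=grad, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 500})
    z = D @ res.x
    w = np.exp(z - logsumexp(z))
    if not np.all(np.isfinite(w)) or np.max(np.abs(w @ D)) > 1e-6:
        raise ValueError("no exact-balance solution (treated outside control hull)")
    return w / w.sum()


def mahalanobis_nn_weights(
    x_treated: np.ndarray,
    X_controls: np.ndarray,
    control_names: list[str],
    j: int,
) -> np.ndarray:
    """Uniform weights on the J Mahalanobis-nearest controls.

    Ties are broken by lexicographic control name for determinism.
    """
    diffs = X_controls - x_treated
    cov = np.cov(X_controls, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-8 * np.eye(X_controls.shape[1])
    vi = np.linalg.pinv(cov)
    d = np.einsum("ip,pq,iq->i", diffs, vi, diffs)
    order = sorted(range(len(d)), key=lambda i: (d[i], control_names[i]))
    keep = order[: max(1, min(j, len(order)))]
    w = np.zeros(len(d))
    w[keep] = 1.0 / len(keep)
    return w


def cbps_propensity(X: np.ndarray, treated: np.ndarray) -> np.ndarray:
    """Just-identified covariate-balancing propensity scores (ATT moments).

    Finds logistic coefficients beta so that odds-weighted control covariate
    means equal the treated means: Σ_T x / n_T = Σ_C o(x) x / Σ_C o(x) with
    o(x) = e(x)/(1−e(x)). Falls back to plain logistic scores when the
    balance system cannot be solved.
    """
    Xd = np.c_[np.ones(len(X)), X]
    t = treated.astype(bool)
    xbar_t = Xd[t].mean(axis=0)

    def moments(beta):
        eta = Xd @ beta
        odds = np.exp(np.clip(eta, -30, 30))
        wc = odds[~t]
        return xbar_t - (wc @ Xd[~t]) / wc.sum()

    beta0 = _logit_coefs(Xd, t)
    sol = optimize.root(moments, beta0, method="hybr")
    beta = sol.x if sol.success and np.max(np.abs(moments(sol.x))) < 1e-6 else None
    if beta is None:
        warnings.warn("CBPS balance system not solved; using logistic propensity")
        beta = beta0
    return np.clip(expit(Xd @ beta), 1e-8, 1 - 1e-8)


def _logit_coefs(Xd: np.ndarray, t: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.Logit(t.astype(float), Xd).fit(disp=0, maxiter=200).params
        except Exception:  # separation / singular design
            return sm.Logit(t.astype(float), Xd).fit_regularized(
                alpha=1e-4, disp=0
            ).params


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_feature_array(
    Y: np.ndarray,
    covariates: np.ndarray | None,
    L: int,
    condition_on_pre_outcomes: bool = True,
) -> np.ndarray:
    """Per (unit, t) matching features: covariates at t−1 plus outcome lags.

    ``covariates`` has shape (S, Q, p) or None. Returns (S, Q, p+L) with NaN
    where lags run off the window; features are z-scored over finite entries
    so that optimisation is well conditioned (affine rescaling does not
    change what exact balance means).
    """
    S, Q = Y.shape
    blocks = []
    if covariates is not None:
        lagged = np.full_like(covariates, np.nan, dtype=float)
        lagged[:, 1:, :] = covariates[:, :-1, :]
        blocks.append(lagged)
    if condition_on_pre_outcomes:
        lags = np.full((S, Q, L), np.nan)
        for ell in range(1, L + 1):
            lags[:, ell:, ell - 1] = Y[:, :-ell] if ell else Y
        blocks.append(lags)
    if not blocks:
        raise ValueError("no features: need covariates or pre-outcome lags")
    F = np.concatenate(blocks, axis=2)
    flat = F.reshape(-1, F.shape[2])
    mu = np.nanmean(flat, axis=0)
    sd = np.nanstd(flat, axis=0)
    sd[sd == 0] = 1.0
    return (F - mu) / sd


def refine_sets_array(
    sets: list[tuple[int, int, np.ndarray]],
    features: np.ndarray | None,
    method: str = "cbps",
    j: int = 3,
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Attach refinement weights to raw (treated, t, controls) triples."""
    if method in (None, "none", "uniform") or features is None:
        return _uniform(sets)
    refined = []
    if method == "cbps":
        rows_t, rows_c, owner = [], [], []
        for k, (tr, t, ctrl) in enumerate(sets):
            if len(ctrl) == 0:
                continue
            rows_t.append(features[tr, t])
            for c in ctrl:
                rows_c.append(features[c, t])
                owner.append(k)
        if not rows_c:
            return _uniform(sets)
        X = np.vstack(rows_t + rows_c)
        lab = np.r_[np.ones(len(rows_t)), np.zeros(len(rows_c))]
        ok = np.all(np.isfinite(X), axis=1)
        if not ok.all():  # drop unusable rows from the pooled fit only
            X, lab = X[ok], lab[ok]
        e = cbps_propensity(X, lab.astype(bool))
        odds_all = np.full(len(rows_t) + len(rows_c), np.nan)
        odds_all[ok] = e / np.clip(1 - e, 1e-12, None)
        odds_c = odds_all[len(rows_t):]
        per_set: dict[int, list[float]] = {}
        for o, k in zip(odds_c, owner):
            per_set.setdefault(k, []).append(o if np.isfinite(o) else 1.0)
        for k, (tr, t, ctrl) in enumerate(sets):
            if len(ctrl) == 0:
                refined.append((tr, t, ctrl, np.empty(0)))
                continue
            w = np.asarray(per_set[k], dtype=float)
            if np.all(np.isfinite(w)) and w.sum() > 0:
                w = w / w.sum()
            else:  # separation / degenerate design: uniform fallback
                warnings.warn("degenerate propensity weights in a matched set; "
                              "falling back to uniform")
                w = np.full(len(ctrl), 1.0 / len(ctrl))
            refined.append((tr, t, ctrl, w))
        return refined
    for tr, t, ctrl in sets:
        if len(ctrl) == 0:
            refined.append((tr, t, ctrl, np.empty(0)))
            continue
        x_t = features[tr, t]
        X_c = features[ctrl, t]
        ok = np.isfinite(x_t).all() and np.all(np.isfinite(X_c))
        w = None
        if ok and len(ctrl) > 1:
            try:
                if method == "entropy":
                    w = entropy_weights(x_t, X_c)
                elif method == "nn":
                    w = mahalanobis_nn_weights(x_t, X_c, [str(c) for c in ctrl], j)
                elif method == "ipw":
                    X = np.vstack([x_t, X_c])
                    lab = np.r_[1.0, np.zeros(len(ctrl))]
                    e = expit(np.c_[np.ones(len(X)), X] @ _logit_coefs(
                        np.c_[np.ones(len(X)), X], lab.astype(bool)))
                    o = e[1:] / np.clip(1 - e[1:], 1e-12, None)
                    w = o / o.sum()
                else:
                    raise ValueError(f"unknown refinement method: {method!r}")
            except ValueError as exc:
                if "unknown refinement" in str(exc):
                    raise
                warnings.warn(f"refinement failed for set (unit {tr}, t={t}); "
                              f"using uniform weights: {exc}")
                w = None
        if w is None:
            w = np.full(len(ctrl), 1.0 / len(ctrl))
        refined.append((tr, t, ctrl, w))
    return refined


# ---------------------------------------------------------------------------
# public API on labelled panels
# ---------------------------------------------------------------------------

def find_matched_sets(treat_wide: pd.DataFrame, L: int = DEFAULT_LAG) -> list[MatchedSet]:
    """Matched sets (uniform weights) from a wide states × quarters 0/1 panel.

    Sets with an empty control pool are returned too (``empty=True``) so the
    caller can report how many treated events went unmatched; estimation
    drops them.
    """
    treat_wide = treat_wide.sort_index()
    T = treat_wide.to_numpy(dtype=np.int8)
    if (np.diff(T, axis=1) < 0).any():
        raise ValueError("treatment panel is not absorbing")
    states = list(treat_wide.index)
    out = []
    for s, t, ctrl in _sets_array(T, L):
        w = np.full(len(ctrl), 1.0 / len(ctrl)) if len(ctrl) else np.empty(0)
        out.append(MatchedSet(states[s], int(t), [states[c] for c in ctrl], w))
    return out


def refine_weights(
    msets: list[MatchedSet],
    outcome_wide: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    L: int = DEFAULT_LAG,
    method: str = "cbps",
    j: int = 3,
    condition_on_pre_outcomes: bool = True,
) -> list[MatchedSet]:
    """Replace each set's uniform weights with covariate-balancing weights.

    ``covariates`` is a long (state, quarter, feature...) table; features are
    the covariate values at t−1 plus L pre-treatment outcome lags.
    """
    outcome_wide = outcome_wide.sort_index()
    states = list(outcome_wide.index)
    pos = {s: i for i, s in enumerate(states)}
    cov_arr = None
    if covariates is not None:
        cols = [c for c in covariates.columns if c not in ("state", "quarter")]
        wide = covariates.set_index(["state", "quarter"]).sort_index()
        Q = outcome_wide.shape[1]
        cov_arr = np.full((len(states), Q, len(cols)), np.nan)
        for i, s in enumerate(states):
            block = wide.loc[s, cols].reindex(range(Q))
            cov_arr[i] = block.to_numpy(dtype=float)
    features = build_feature_array(
        outcome_wide.to_numpy(dtype=float), cov_arr, L, condition_on_pre_outcomes
    )
    triples = [
        (pos[m.treated_state], m.t, np.array([pos[c] for c in m.controls], dtype=int))
        for m in msets
    ]
    refined = refine_sets_array(triples, features, method=method, j=j)
    return [
        replace(m, weights=w, controls=[states[c] for c in ctrl])
        for m, (_, _, ctrl, w) in zip(msets, refined)
    ]


def att_at_lead(
    msets: list[MatchedSet],
    outcome_wide: pd.DataFrame,
    lead: int,
    treat_wide: pd.DataFrame | None = None,
    policy_type: str = "",
    outcome: str = "",
) -> ATTEstimate:
    """Point estimate of the average per-set DiD at one lead (no CI).

    When ``treat_wide`` is supplied, controls that become treated by t+lead
    are excluded from the contrast at that lead (weights renormalised).
    """
    outcome_wide = outcome_wide.sort_index()
    pos = {s: i for i, s in enumerate(outcome_wide.index)}
    Y = outcome_wide.to_numpy(dtype=float)
    adopt = None
    if treat_wide is not None:
        adopt = _first_adoption(
            treat_wide.sort_index().reindex(outcome_wide.index).to_numpy(np.int8)
        )
    triples = [
        (pos[m.treated_state], m.t, np.array([pos[c] for c in m.controls], dtype=int),
         m.weights)
        for m in msets if not m.empty
    ]
    est, n = _att_profile_array(triples, Y, lead, adopt=adopt)
    return ATTEstimate(policy_type, outcome, lead, float(est[lead]), n_sets=int(n[lead]))


def bootstrap_ci(
    treat_wide: pd.DataFrame,
    outcome_wide: pd.DataFrame,
    L: int = DEFAULT_LAG,
    f_max: int = DEFAULT_F_MAX,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    covariates: pd.DataFrame | None = None,
    method: str = "uniform",
    j: int = 3,
    condition_on_pre_outcomes: bool = True,
    policy_type: str = "",
    outcome: str = "",
    return_draws: bool = False,
) -> list[ATTEstimate] | tuple[list[ATTEstimate], np.ndarray]:
    """Lead-profile ATT with block-bootstrap percentile CIs.

    Whole state trajectories are resampled with replacement; matched sets,
    refinement and the DiD contrast are recomputed inside every replicate.
    Replicates in which no matched set exists at a lead contribute a missing
    draw there (counted in the log).
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    treat_wide = treat_wide.sort_index()
    outcome_wide = outcome_wide.reindex(treat_wide.index)
    T = treat_wide.to_numpy(dtype=np.int8)
    Y = outcome_wide.to_numpy(dtype=float)
    S = T.shape[0]

    cov_arr = None
    if covariates is not None:
        cols = [c for c in covariates.columns if c not in ("state", "quarter")]
        widec = covariates.set_index(["state", "quarter"]).sort_index()
        cov_arr = np.full((S, T.shape[1], len(cols)), np.nan)
        for i, s in enumerate(treat_wide.index):
            cov_arr[i] = widec.loc[s, cols].reindex(range(T.shape[1])).to_numpy(float)

    def profile(Tm, Ym, Cm):
        sets = _sets_array(Tm, L)
        if method in (None, "none", "uniform"):
            wsets = _uniform(sets)
        else:
            feats = build_feature_array(Ym, Cm, L, condition_on_pre_outcomes)
            wsets = refine_sets_array(sets, feats, method=method, j=j)
        return _att_profile_array(wsets, Ym, f_max, adopt=_first_adoption(Tm))

    point, n_sets = profile(T, Y, cov_arr)
    draws = np.full((B, f_max + 1), np.nan)
    for b in range(B):
        idx = rng.integers(0, S, S)
        draws[b] = profile(
            T[idx], Y[idx], cov_arr[idx] if cov_arr is not None else None
        )[0]
    n_missing = int(np.isnan(draws).all(axis=1).sum())
    if n_missing:
        logger.info("%d/%d bootstrap replicates had no matched sets", n_missing, B)

    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(draws, 100 * alpha / 2, axis=0)
        hi = np.nanpercentile(draws, 100 * (1 - alpha / 2), axis=0)
        se = np.nanstd(draws, axis=0, ddof=1)
    for f in range(f_max + 1):
        out.append(
            ATTEstimate(policy_type, outcome, f, float(point[f]), float(se[f]),
                        float(lo[f]), float(hi[f]), int(n_sets[f]))
        )
    return (out, draws) if return_draws else out
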