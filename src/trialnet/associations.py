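"""Composite-network association machinery.

Implements the correlation grid with Fisher-z confidence intervals, per-network
multiple regression with LMG relative importance and variance inflation
factors, Difficulty residualization, response-time validation of the
Difficulty composite, extreme-trial contrast maps with network-overlap
statistics, Welch subset tests, and the 2x2 double-dissociation summary.

LMG relative importance decomposes a model's R^2 into per-regressor shares by
averaging each regressor's incremental R^2 over all orders of entry; shares
sum exactly to the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RT_OUTLIER_SECONDS = 60.0


@dataclass
class CorrelationResult:
    predictor: str
    network: str
    n: int
    r: float
    ci_low: float
    ci_high: float
    p: float
    residualized: bool = False


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% CI for a Pearson correlation via the Fisher z transform."""
    if n < 4:
        raise ValueError("Fisher CI requires n >= 4")
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate_pair(
    x: np.ndarray, y: np.ndarray, predictor: str, network: str, residualized: bool = False
) -> CorrelationResult:
    n = len(x)
    r, p = stats.pearsonr(x, y)
    lo, hi = fisher_ci(float(r), n)
    return CorrelationResult(
        predictor=predictor,
        network=network,
        n=n,
        r=float(r),
        ci_low=lo,
        ci_high=hi,
        p=float(p),
        residualized=residualized,
    )


def correlate_predictors_networks(
    predictors: pd.DataFrame,
    responses: pd.DataFrame,
    residualized: bool = False,
) -> pd.DataFrame:
    """Pearson r (+ Fisher CI, two-sided p) for every predictor-network pair.

    Rows are aligned on trial id; predictors may be composites or individual
    strategy probes.
    """
    shared = predictors.index.intersection(responses.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared trials")
    px, ry = predictors.loc[shared], responses.loc[shared]
    rows = [
        vars(correlate_pair(px[c].to_numpy(), ry[net].to_numpy(), c, net, residualized))
        for c in px.columns
        for net in ry.columns
    ]
    return pd.DataFrame(rows)


@dataclass
class ModelFit:
    network: str
    regressors: list[str]
    coef: pd.Series
    coef_p: pd.Series
    r2: float
    f: float
    df1: int
    df2: int
    f_p: float
    lmg: pd.Series  # per-regressor R^2 share; sums to r2
    vif: pd.Series


def _subset_r2(y: np.ndarray, x: np.ndarray, cache: dict, idx: tuple[int, ...]) -> float:
    if idx in cache:
        return cache[idx]
    if not idx:
        cache[idx] = 0.0
        return 0.0
    design = sm.add_constant(x[:, list(idx)])
    r2 = float(sm.OLS(y, design).fit().rsquared)
    cache[idx] = r2
    return r2


def lmg_importance(y: np.ndarray, x: np.ndarray, names: list[str]) -> pd.Series:
    """Ordering-averaged incremental R^2 per regressor (LMG shares).

    Computed by subset weighting: share_j = sum over subsets S of the other
    regressors of w(|S|) * [R^2(S + j) - R^2(S)] with
    w(k) = k! (p - k - 1)! / p!, equivalent to the explicit average over all
    p! orders of entry. Limited to p <= 8 regressors (exhaustive subsets).
    """
    p = x.shape[1]
    if p > 8:
        raise ValueError("LMG subset enumeration limited to 8 regressors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < p + 1:
        raise ValueError("exactly collinear regressors")
    cache: dict[tuple[int, ...], float] = {}
    shares = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in combinations(rest, size):
                base = _subset_r2(y, x, cache, tuple(sorted(subset)))
                with_j = _subset_r2(y, x, cache, tuple(sorted(subset + (j,))))
                shares[j] += w * (with_j - base)
    return pd.Series(shares, index=names, name="lmg")


def vif(x: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    regressor j on the others (with intercept). Perfect collinearity reports
    infinity. Values above 3 conventionally flag problematic intercorrelation."""
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least 2 regressors")
    out = {}
    arr = x.to_numpy(dtype=float)
    for j, name in enumerate(x.columns):
        others = np.delete(arr, j, axis=1)
        r2 = float(sm.OLS(arr[:, j], sm.add_constant(others)).fit().rsquared)
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def fit_network_model(
    response: pd.Series, composites: pd.DataFrame, network: str = ""
) -> ModelFit:
    """OLS of one network's trial response on composite scores, with LMG
    relative-importance shares and VIFs."""
    shared = response.index.intersection(composites.index)
    y = response.loc[shared].to_numpy(dtype=float)
    x_df = composites.loc[shared]
    if len(y) <= x_df.shape[1] + 1:
        raise ValueError("too few trials for the number of regressors")
    x = x_df.to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    names = list(x_df.columns)
    return ModelFit(
        network=network or str(response.name),
        regressors=names,
        coef=pd.Series(fit.params[1:], index=names),
        coef_p=pd.Series(fit.pvalues[1:], index=names),
        r2=float(fit.rsquared),
        f=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        f_p=float(fit.f_pvalue),
        lmg=lmg_importance(y, x, names),
        vif=vif(x_df) if x_df.shape[1] >= 2 else pd.Series(1.0, index=names),
    )


def residualize_composites(scores: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Replace every other composite by its OLS residuals on ``covariate``
    (with intercept); the covariate column is dropped from the result."""
    if covariate not in scores.columns:
        raise ValueError(f"covariate {covariate} not in score table")
    cov = scores[covariate].to_numpy(dtype=float)
    if np.std(cov) == 0:
        raise ValueError("zero-variance covariate")
    design = sm.add_constant(cov)
    out = {}
    for col in scores.columns:
        if col == covariate:
            continue
        out[col] = sm.OLS(scores[col].to_numpy(dtype=float), design).fit().resid
    return pd.DataFrame(out, index=scores.index)


def rt_validation(
    rts: pd.DataFrame, difficulty: pd.Series, outlier_seconds: float = RT_OUTLIER_SECONDS
) -> CorrelationResult:
    """Correlate per-trial mean response times with the Difficulty composite.

    ``rts`` is long (trial_id, response_time); individual responses above
    ``outlier_seconds`` are dropped before trial means.
    """
    keep = rts[rts["response_time"] <= outlier_seconds]
    if keep.empty:
        raise ValueError("all response times excluded as outliers")
    mean_rt = keep.groupby("trial_id")["response_time"].mean()
    shared = mean_rt.index.intersection(difficulty.index)
    return correlate_pair(
        difficulty.loc[shared].to_numpy(),
        mean_rt.loc[shared].to_numpy(),
        predictor="Difficulty",
        network="mean_RT",
    )


@dataclass
class ContrastSpec:
    composite: str
    n_extreme: int
    high: tuple[int, ...]
    low: tuple[int, ...]
    role_filter: str | None = None


def select_extreme_trials(
    scores: pd.DataFrame,
    composite: str,
    n_extreme: int = 10,
    metadata: pd.DataFrame | None = None,
    role: str | None = None,
) -> ContrastSpec:
    """Top and bottom ``n_extreme`` trials by composite score, optionally
    restricted to one trial role; ties break by trial id (stable)."""
    s = scores[composite]
    if role is not None:
        if metadata is None:
            raise ValueError("role filter requires trial metadata")
        eligible = metadata.loc[metadata["role"] == role, "trial_id"]
        s = s.loc[s.index.intersection(eligible)]
    if len(s) < 2 * n_extreme:
        raise ValueError("not enough eligible trials")
    ordered = s.to_frame("score").reset_index()
    ordered = ordered.sort_values(["score", "trial_id"], kind="mergesort")
    low = tuple(ordered["trial_id"].head(n_extreme))
    high = tuple(ordered["trial_id"].tail(n_extreme))
    return ContrastSpec(
        composite=composite, n_extreme=n_extreme, high=high, low=low, role_filter=role
    )


@dataclass
class ContrastMap:
    subject: str
    values: np.ndarray  # per-vertex mean(high) - mean(low)
    target_network: str
    mean_inside: float
    mean_outside: float
    dice: float


def compute_contrast_map(
    betas: np.ndarray,
    trial_ids: np.ndarray,
    spec: ContrastSpec,
    labels: np.ndarray,
    target_network: str,
    subject: str = "",
) -> ContrastMap:
    """Vertexwise mean(high trials) - mean(low trials) with overlap statistics
    against the subject's target-network label: mean inside vs outside the
    border, and Dice between the top-q thresholded map and the label
    (q = label size)."""
    if betas.shape[1] != len(labels):
        raise ValueError("betas and labels disagree on vertex count")
    index = {t: i for i, t in enumerate(trial_ids)}
    try:
        hi = [index[t] for t in spec.high]
        lo = [index[t] for t in spec.low]
    except KeyError as err:
        raise ValueError(f"spec trial missing from betas: {err}") from err
    cmap = betas[hi].mean(axis=0) - betas[lo].mean(axis=0)
    inside = labels == target_network
    if not inside.any():
        raise ValueError(f"target network {target_network} has no vertices")
    q = int(inside.sum())
    top = np.zeros(len(cmap), dtype=bool)
    top[np.argsort(cmap, kind="mergesort")[-q:]] = True
    dice = 2.0 * (top & inside).sum() / (top.sum() + inside.sum())
    return ContrastMap(
        subject=subject,
        values=cmap,
        target_network=target_network,
        mean_inside=float(cmap[inside].mean()),
        mean_outside=float(cmap[~inside].mean()),
        dice=float(dice),
    )


@dataclass
class SubsetTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float


def subset_t_test(values_a: np.ndarray, values_b: np.ndarray) -> SubsetTestResult:
    """Welch two-sample t test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each subset needs at least 2 trials")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return SubsetTestResult(0.0, float(len(a) + len(b) - 2), 1.0, a.mean(), b.mean())
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return SubsetTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def extreme_quadrant_subsets(
    scores: pd.DataFrame,
    composite_a: str,
    composite_b: str,
    n_per_side: int = 7,
    metadata: pd.DataFrame | None = None,
    role: str | None = None,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Trials most extreme along the ``composite_a`` minus ``composite_b`` axis.

    Both composites are standardized over the eligible trials; the first
    returned tuple holds the ``n_per_side`` trials highest on a relative to b
    (the a-leaning quadrant), the second the ``n_per_side`` lowest. Ties break
    by trial id."""
    sub = scores
    if role is not None:
        if metadata is None:
            raise ValueError("role filter requires trial metadata")
        eligible = metadata.loc[metadata["role"] == role, "trial_id"]
        sub = scores.loc[scores.index.intersection(eligible)]
    za = (sub[composite_a] - sub[composite_a].mean()) / sub[composite_a].std(ddof=1)
    zb = (sub[composite_b] - sub[composite_b].mean()) / sub[composite_b].std(ddof=1)
    axis = (za - zb).to_frame("delta").reset_index()
    axis = axis.sort_values(["delta", "trial_id"], kind="mergesort")
    if len(axis) < 2 * n_per_side:
        raise ValueError("not enough eligible trials")
    side_a = tuple(axis["trial_id"].tail(n_per_side))
    side_b = tuple(axis["trial_id"].head(n_per_side))
    return side_a, side_b


def dissociation_report(
    grid: pd.DataFrame,
    predictors: tuple[str, str],
    networks: tuple[str, str],
) -> pd.DataFrame:
    """2x2 slice of the correlation grid for a candidate double dissociation.

    Adds a ``selective`` flag: True when each network's on-target |r| exceeds
    its off-target |r| and the predictors are not identical columns."""
    rows = []
    for pred in predictors:
        for net in networks:
            cell = grid[(grid["predictor"] == pred) & (grid["network"] == net)]
            if cell.empty:
                raise ValueError(f"grid missing cell ({pred}, {net})")
            rows.append(cell.iloc[0])
    table = pd.DataFrame(rows).reset_index(drop=True)
    r = table.set_index(["predictor", "network"])["r"]
    p0, p1 = predictors
    n0, n1 = networks
    on = (abs(r[(p0, n0)]), abs(r[(p1, n1)]))
    off = (abs(r[(p1, n0)]), abs(r[(p0, n1)]))
    table.attrs["selective"] = bool(on[0] > off[0] and on[1] > off[1])
    return table
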