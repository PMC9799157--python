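"""Reliability estimation: inter-experiment correlations, split-half
reliability with Spearman-Brown adjustment, and the explainable-variance
ceiling.

Split-half reliability of a mean over n units (raters or scanned subjects) is
estimated by correlating mean vectors from two balanced halves across
observations (trials) and stepping the half-length correlation up to the full
sample with the Spearman-Brown prophecy formula r' = 2r / (1 + r).
The product of two measures' reliabilities bounds the R^2 any true
relationship between them could produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


def spearman_brown(r: float, lengthening: float = 2.0) -> float:
    """Prophecy formula: reliability after lengthening the test k-fold."""
    return lengthening * r / (1.0 + (lengthening - 1.0) * r)


@dataclass
class ReliabilityEstimate:
    raw_r: float
    adjusted_r: float
    scheme: str
    n_splits: int
    n_units: int
    seed: int | None
    aggregation: str


@dataclass
class ExplainableVariance:
    rel_x: float
    rel_y: float
    ceiling: float
    observed_r2: float
    fraction: float


def trialwise_interexperiment_reliability(
    profiles_exp1: pd.DataFrame, profiles_exp2: pd.DataFrame
) -> pd.Series:
    """Per-trial Pearson r between the two experiments' 16 strategy means."""
    m1 = profiles_exp1.pivot(index="trial_id", columns="strategy", values="mean")
    m2 = profiles_exp2.pivot(index="trial_id", columns="strategy", values="mean")
    if set(m1.columns) != set(m2.columns):
        raise ValueError("experiments measured different strategy sets")
    m2 = m2[m1.columns].loc[m1.index]
    if (m1.std(axis=1, ddof=1) == 0).any() or (m2.std(axis=1, ddof=1) == 0).any():
        raise ValueError("zero-variance trial profile")
    r = m1.corrwith(m2, axis=1, method="pearson")
    r.name = "r"
    return r


def probewise_interexperiment_reliability(
    matrix_exp1: pd.DataFrame, matrix_exp2: pd.DataFrame
) -> pd.Series:
    """Per-probe Pearson r between the two experiments' trial-mean vectors."""
    if list(matrix_exp1.columns) != list(matrix_exp2.columns):
        if set(matrix_exp1.columns) != set(matrix_exp2.columns):
            raise ValueError("experiments cover different trial sets")
        matrix_exp2 = matrix_exp2[matrix_exp1.columns]
    if list(matrix_exp1.index) != list(matrix_exp2.index):
        raise ValueError("strategy rows must match")
    r = matrix_exp1.corrwith(matrix_exp2, axis=1, method="pearson")
    r.name = "r"
    return r


def _balanced_partitions_all(n: int):
    """All distinct balanced half-partitions of range(n); n even."""
    half = n // 2
    first = 0
    for combo in combinations(range(1, n), half - 1):
        a = np.array((first, *combo))
        mask = np.zeros(n, dtype=bool)
        mask[a] = True
        yield mask


def split_half_reliability(
    table: pd.DataFrame,
    scheme: str = "all-combinations",
    n_splits: int = 1000,
    seed: int | None = 0,
    max_units: int | None = None,
    aggregation: str = "fisher_before_sb",
) -> ReliabilityEstimate:
    """Split-half reliability of the unit-mean over a units x observations table.

    Per split, the two halves' mean vectors are correlated across
    observations; per-split correlations are Fisher-z averaged and then
    Spearman-Brown adjusted (or adjusted first, ``aggregation='sb_before_mean'``).
    ``all-combinations`` enumerates every balanced partition (126 for 10
    units); ``random-resample`` draws ``n_splits`` balanced partitions, by
    convention from the first ``max_units`` units.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    values = table.to_numpy(dtype=float)
    if max_units is not None and values.shape[0] > max_units:
        values = values[:max_units]
    n = values.shape[0]

    def split_r(mask: np.ndarray) -> float:
        a = values[mask].mean(axis=0)
        b = values[~mask].mean(axis=0)
        return float(np.corrcoef(a, b)[0, 1])

    rs: list[float] = []
    if scheme == "all-combinations":
        work = values
        if n % 2:
            drop = rng.integers(n)
            work = np.delete(values, drop, axis=0)
            n -= 1
        sub = work

        def split_r(mask: np.ndarray) -> float:  # noqa: F811 - rebind over sub
            return float(np.corrcoef(sub[mask].mean(axis=0), sub[~mask].mean(axis=0))[0, 1])

        masks = list(_balanced_partitions_all(n))
        rs = [split_r(m) for m in masks]
        n_used = len(masks)
    elif scheme == "random-resample":
        for _ in range(n_splits):
            idx = rng.permutation(n)
            if len(idx) % 2:
                idx = idx[:-1]  # drop one unit at random (permutation is random)
            mask = np.zeros(n, dtype=bool)
            mask[idx[: len(idx) // 2]] = True
            keep = np.zeros(n, dtype=bool)
            keep[idx] = True
            a = values[mask & keep].mean(axis=0)
            b = values[~mask & keep].mean(axis=0)
            rs.append(float(np.corrcoef(a, b)[0, 1]))
        n_used = n_splits
    else:
        raise ValueError(f"unknown scheme: {scheme}")

    rs_arr = np.asarray(rs)
    with np.errstate(divide="ignore"):
        if aggregation == "fisher_before_sb":
            raw = float(np.tanh(np.mean(np.arctanh(np.clip(rs_arr, -1.0, 1.0)))))
            adjusted = spearman_brown(raw)
        elif aggregation == "sb_before_mean":
            adj = np.array([spearman_brown(r) for r in rs_arr])
            adjusted = float(np.tanh(np.mean(np.arctanh(np.clip(adj, -1.0, 1.0)))))
            raw = float(np.tanh(np.mean(np.arctanh(np.clip(rs_arr, -1.0, 1.0)))))
        else:
            raise ValueError(f"unknown aggregation: {aggregation}")
    return ReliabilityEstimate(
        raw_r=raw,
        adjusted_r=adjusted,
        scheme=scheme,
        n_splits=n_used,
        n_units=n,
        seed=seed,
        aggregation=aggregation,
    )


def composite_split_half(
    ratings_long: pd.DataFrame,
    members: tuple[str, ...],
    n_splits: int = 1000,
    seed: int | None = 0,
    max_units: int = 36,
) -> ReliabilityEstimate:
    """Split-half reliability of a composite score over rater halves.

    ``ratings_long`` has one row per rater x trial with the member strategy
    columns. Per trial, the first ``max_units`` raters (by rater id) fill the
    unit slots. Per split, each half's per-trial strategy means are z-scored
    within strategy across trials and summed over members — the full
    composite recipe — and the two half composites are correlated across
    trials; per-split r is Fisher-z averaged then Spearman-Brown adjusted.
    """
    members = tuple(members)
    ordered = ratings_long.sort_values(["trial_id", "rater_id"], kind="mergesort")
    counts = ordered.groupby("trial_id").size()
    n_slots = min(int(counts.min()), max_units)
    if n_slots < 2:
        raise ValueError("need at least 2 raters per trial")
    if n_slots % 2:
        n_slots -= 1
    head = ordered.groupby("trial_id").head(n_slots)
    trial_ids = counts.index.to_numpy()
    # slots x trials x members
    cube = (
        head[list(members)]
        .to_numpy(dtype=float)
        .reshape(len(trial_ids), n_slots, len(members))
        .transpose(1, 0, 2)
    )
    rng = np.random.default_rng(seed)

    def half_composite(block: np.ndarray) -> np.ndarray:
        means = block.mean(axis=0)  # trials x members
        z = (means - means.mean(axis=0)) / means.std(axis=0, ddof=1)
        return z.sum(axis=1)

    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(n_slots)
        a, b = perm[: n_slots // 2], perm[n_slots // 2 :]
        rs.append(
            float(np.corrcoef(half_composite(cube[a]), half_composite(cube[b]))[0, 1])
        )
    with np.errstate(divide="ignore"):
        raw = float(np.tanh(np.mean(np.arctanh(np.clip(np.asarray(rs), -1.0, 1.0)))))
    return ReliabilityEstimate(
        raw_r=raw,
        adjusted_r=spearman_brown(raw),
        scheme="random-resample",
        n_splits=n_splits,
        n_units=n_slots,
        seed=seed,
        aggregation="fisher_before_sb",
    )


def explainable_variance_fraction(
    r2: float, rel_x: float, rel_y: float
) -> ExplainableVariance:
    """Ceiling = rel_x * rel_y; fraction = observed R^2 / ceiling."""
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be positive")
    ceiling = rel_x * rel_y
    fraction = r2 / ceiling
    if fraction > 1:
        warnings.warn(
            f"observed R^2 {r2:.3f} exceeds explainable ceiling {ceiling:.3f}",
            stacklevel=2,
        )
    return ExplainableVariance(
        rel_x=rel_x, rel_y=rel_y, ceiling=ceiling, observed_r2=r2, fraction=fraction
    )
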