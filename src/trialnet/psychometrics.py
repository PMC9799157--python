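"""Trial-level strategy profiles, the z-scored strategy matrix, replicated
hierarchical clustering, and composite scores.

The clustering step mirrors the classical workflow: Pearson correlations among
the 16 z-scored strategy rows across all trials, distance ``d = 1 - r``, Ward
minimum-variance agglomeration, and a dendrogram cut at the height of a
reference pair so that every cluster at least as strong as that pair survives.
Replicated clusterings from two independent rater samples are reconciled by
intersecting their co-membership graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .constants import STRATEGIES
from .sessions import RaterSession


@dataclass
class StrategyMatrix:
    """Strategies x trials matrix of z-scored mean ratings."""

    values: pd.DataFrame  # index: strategy, columns: trial_id
    provenance: str = ""

    @property
    def strategies(self) -> list[str]:
        return list(self.values.index)

    @property
    def trial_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Merge sequence in scipy linkage form plus ordered leaf names."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class CompositeDefinition:
    name: str
    members: tuple[str, ...]


@dataclass
class CompositeScores:
    values: pd.DataFrame  # index: trial_id, columns: composite
    definitions: list[CompositeDefinition] = field(default_factory=list)


def aggregate_trial_profiles(
    kept_sessions: list[RaterSession],
    trial_metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean and standard error per strategy per trial, pooled over raters.

    Returns a long frame with columns trial_id, strategy, mean, se, n_raters
    (plus condition/role when metadata is supplied). Repeated administrations
    of a trial are pooled across raters.
    """
    if not kept_sessions:
        raise ValueError("no sessions supplied")
    long = pd.concat(
        [s.trials[["trial_id", *STRATEGIES]] for s in kept_sessions],
        ignore_index=True,
    ).melt(id_vars="trial_id", var_name="strategy", value_name="rating")
    g = long.groupby(["trial_id", "strategy"], sort=True)["rating"]
    prof = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n_raters="count").reset_index()
    if (prof["n_raters"] < 1).any():
        raise ValueError("trial with no raters")
    single = prof["n_raters"] == 1
    if single.any():
        warnings.warn("trials with a single rater: SE reported as 0", stacklevel=2)
        prof.loc[single, "sd"] = 0.0
    prof["se"] = prof["sd"] / np.sqrt(prof["n_raters"])
    prof = prof.drop(columns="sd")
    if trial_metadata is not None:
        prof = prof.merge(
            trial_metadata[["trial_id", "condition", "role"]], on="trial_id", how="left"
        )
    return prof


def profiles_to_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pivot long profiles into a raw strategies x trials mean-rating matrix."""
    mat = profiles.pivot(index="strategy", columns="trial_id", values="mean")
    return mat.reindex([s for s in STRATEGIES if s in mat.index])


def zscore_within_strategy(
    profiles: pd.DataFrame, provenance: str = ""
) -> StrategyMatrix:
    """Standardize each strategy's mean ratings across trials (sample sd)."""
    raw = profiles_to_matrix(profiles) if "strategy" in profiles.columns else profiles
    if raw.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 trials")
    sd = raw.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance strategies set to all-zero: {list(raw.index[degenerate])}",
            stacklevel=2,
        )
    z = raw.sub(raw.mean(axis=1), axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z[degenerate] = 0.0
    return StrategyMatrix(values=z, provenance=provenance)


def strategy_correlation_matrix(matrix: StrategyMatrix) -> pd.DataFrame:
    """Pearson correlations between strategy rows, across trials."""
    values = matrix.values
    if (values.std(axis=1, ddof=1) == 0).any():
        raise ValueError("zero-variance strategy row")
    corr = values.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_strategies(corr: pd.DataFrame) -> Dendrogram:
    """Ward agglomeration on correlation distance ``d = 1 - r``.

    Leaves are pre-sorted lexicographically so that exact merge-height ties
    resolve deterministically by name.
    """
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    order = sorted(corr.index)
    d = 1.0 - corr.loc[order, order].to_numpy()
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return Dendrogram(linkage=link, leaves=list(order))


def cut_at_reference_pair(
    dendrogram: Dendrogram, pair: tuple[str, str] = ("Facts", "Difficulty")
) -> list[frozenset[str]]:
    """Cut just above the smallest cluster containing both reference leaves,
    preserving every cluster at least as strong (merged lower) than the pair.
    """
    leaves = dendrogram.leaves
    n = len(leaves)
    if n < 2:
        raise ValueError("dendrogram must have at least 2 leaves")
    for member in pair:
        if member not in leaves:
            raise ValueError(f"reference pair member not a leaf: {member}")
    members: dict[int, set[str]] = {i: {name} for i, name in enumerate(leaves)}
    pair_set = set(pair)
    height = None
    for k, (a, b, h, _size) in enumerate(dendrogram.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        if height is None and pair_set <= merged:
            height = h
    if height is None:  # unreachable: the root contains every leaf
        raise ValueError("reference pair never co-clusters")
    assignments = hierarchy.fcluster(
        dendrogram.linkage, t=height * (1 + 1e-9) + 1e-12, criterion="distance"
    )
    clusters: dict[int, set[str]] = {}
    for name, cid in zip(leaves, assignments):
        clusters.setdefault(cid, set()).add(name)
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: sorted(c)[0])


def reconcile_composites(
    clusters_exp1: list[frozenset[str]],
    clusters_exp2: list[frozenset[str]],
    manual_exclusions: tuple[str, ...] = (),
    names: dict[str, str] | None = None,
) -> list[CompositeDefinition]:
    """Composites = connected components (size >= 2) of the co-membership
    graph intersection of two replicated clusterings.

    Two strategies are linked iff they share a cluster in BOTH experiments;
    strategies left as singletons, and any listed manual exclusions, drop out.
    """
    universe1 = set().union(*clusters_exp1)
    universe2 = set().union(*clusters_exp2)
    if universe1 != universe2:
        raise ValueError("clusterings cover different strategy universes")
    g = nx.Graph()
    g.add_nodes_from(universe1 - set(manual_exclusions))

    def pairs(clusters):
        out = set()
        for c in clusters:
            items = sorted(c)
            out.update(
                (a, b) for i, a in enumerate(items) for b in items[i + 1 :]
            )
        return out

    for a, b in pairs(clusters_exp1) & pairs(clusters_exp2):
        if g.has_node(a) and g.has_node(b):
            g.add_edge(a, b)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort()
    defs = []
    used: set[str] = set()
    for comp in comps:
        label = None
        if names:
            label = next((names[s] for s in comp if s in names), None)
        if label is None or label in used:
            label = "/".join(comp)
        used.add(label)
        defs.append(CompositeDefinition(name=label, members=comp))
    return defs


def canonical_composite_definitions() -> list[CompositeDefinition]:
    from .constants import CANONICAL_COMPOSITES

    return [
        CompositeDefinition(name=k, members=tuple(v))
        for k, v in CANONICAL_COMPOSITES.items()
    ]


def composite_scores(
    matrix: StrategyMatrix, definitions: list[CompositeDefinition]
) -> CompositeScores:
    """Per-trial composite scores: exact sums of member z-rows."""
    seen: set[str] = set()
    for d in definitions:
        overlap = seen & set(d.members)
        if overlap:
            raise ValueError(f"strategies in multiple composites: {sorted(overlap)}")
        seen |= set(d.members)
        missing = set(d.members) - set(matrix.strategies)
        if missing:
            raise ValueError(f"composite {d.name} missing strategies: {sorted(missing)}")
    scores = pd.DataFrame(
        {d.name: matrix.values.loc[list(d.members)].sum(axis=0) for d in definitions}
    )
    scores.index.name = "trial_id"
    return CompositeScores(values=scores, definitions=list(definitions))
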