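"""Build trial-level strategy profiles, replicate the hierarchical clustering
in both rater samples, reconcile the clusterings, and score the composites.

The dendrogram from each sample is cut at the (Facts, Difficulty) merge so
every cluster at least as tight as that pair survives; strategies that do not
share a cluster in both samples (plus the configured weak probes) drop out.
Composite scores are sums of z-scored mean ratings from the larger sample.
"""

from __future__ import annotations

import pandas as pd

from _common import load_kept_sessions, load_metadata, parse_args

from trialnet import io as tio
from trialnet.pipeline import COMPOSITE_NAMES
from trialnet.psychometrics import (
    aggregate_trial_profiles,
    cluster_strategies,
    composite_scores,
    cut_at_reference_pair,
    reconcile_composites,
    strategy_correlation_matrix,
    zscore_within_strategy,
)


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "composites"
    out.mkdir(parents=True, exist_ok=True)
    meta = load_metadata(args.results)

    matrices, clusterings = {}, {}
    for label in ("exp1", "exp2"):
        kept = load_kept_sessions(args.results, label)
        prof = aggregate_trial_profiles(kept, meta)
        tio.write_table(prof, out / f"trial_profiles_{label}.tsv")
        mat = zscore_within_strategy(prof, label)
        mat.values.to_csv(out / f"strategy_matrix_{label}.tsv", sep="\t")
        corr = strategy_correlation_matrix(mat)
        corr.to_csv(out / f"strategy_correlations_{label}.tsv", sep="\t")
        dend = cluster_strategies(corr)
        clusterings[label] = cut_at_reference_pair(dend, ("Facts", "Difficulty"))
        matrices[label] = mat
        print(f"{label}: clusters at the reference cut:")
        for c in clusterings[label]:
            if len(c) > 1:
                print("   ", ", ".join(sorted(c)))

    defs = reconcile_composites(
        clusterings["exp1"],
        clusterings["exp2"],
        manual_exclusions=("Specificity", "Moral_Principles"),
        names=COMPOSITE_NAMES,
    )
    tio.write_table(
        pd.DataFrame(
            [{"composite": d.name, "members": ",".join(d.members)} for d in defs]
        ),
        out / "composites.tsv",
    )
    scores = composite_scores(matrices["exp2"], defs)
    scores.values.to_csv(out / "composite_scores.tsv", sep="\t")
    dropped = set(matrices["exp2"].strategies) - {m for d in defs for m in d.members}
    print(f"reconciled composites: {sorted(d.name for d in defs)}")
    print(f"strategies excluded: {sorted(dropped)}")


if __name__ == "__main__":
    main()
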