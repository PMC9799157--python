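"""Quantify measurement stability: trial- and probe-level inter-experiment
reliability, and Spearman-Brown-adjusted split-half reliability of the
composite scores over rater halves.
"""

from __future__ import annotations

import pandas as pd

from _common import load_kept_sessions, parse_args

from trialnet import io as tio
from trialnet.constants import STRATEGIES
from trialnet.psychometrics import aggregate_trial_profiles, profiles_to_matrix
from trialnet.reliability import (
    composite_split_half,
    probewise_interexperiment_reliability,
    trialwise_interexperiment_reliability,
)


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "reliability"
    out.mkdir(parents=True, exist_ok=True)

    profiles = {
        label: aggregate_trial_profiles(load_kept_sessions(args.results, label))
        for label in ("exp1", "exp2")
    }
    trial_r = trialwise_interexperiment_reliability(profiles["exp1"], profiles["exp2"])
    trial_r.to_frame().to_csv(out / "trialwise_reliability.tsv", sep="\t")
    probe_r = probewise_interexperiment_reliability(
        profiles_to_matrix(profiles["exp1"]), profiles_to_matrix(profiles["exp2"])
    )
    probe_r.to_frame().to_csv(out / "probewise_reliability.tsv", sep="\t")
    print(
        f"trial-level inter-experiment reliability: mean r = {trial_r.mean():.2f}, "
        f"{100 * (trial_r > 0.8).mean():.0f}% of trials above 0.80"
    )
    print(
        f"probe-level reliability: min r = {probe_r.min():.2f} ({probe_r.idxmin()}), "
        f"max r = {probe_r.max():.2f}"
    )

    comps = tio.read_table(args.results / "composites/composites.tsv")
    ratings_long = pd.concat(
        [
            s.trials[["trial_id", *STRATEGIES]].assign(rater_id=s.rater_id)
            for s in load_kept_sessions(args.results, "exp2")
        ],
        ignore_index=True,
    )
    rows = []
    for _, row in comps.iterrows():
        est = composite_split_half(
            ratings_long, tuple(row["members"].split(",")),
            n_splits=1000, seed=args.seed + 1,
        )
        rows.append(
            {"composite": row["composite"], "raw_r": est.raw_r, "adjusted_r": est.adjusted_r}
        )
        print(f"split-half (SB-adjusted) {row['composite']}: r = {est.adjusted_r:.2f}")
    tio.write_table(pd.DataFrame(rows), out / "composite_split_half.tsv")


if __name__ == "__main__":
    main()
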