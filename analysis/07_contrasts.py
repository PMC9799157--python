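"""Stringent within-individual checks of the double dissociation: extreme-
trial contrast maps against each subject's own network borders, the
Scene-vs-Autobiographical quadrant subset test on DN-A, and the 2x2
dissociation summary.
"""

from __future__ import annotations

import pandas as pd

from _common import load_metadata, parse_args, study_dir

from trialnet import io as tio
from trialnet.associations import (
    compute_contrast_map,
    dissociation_report,
    extreme_quadrant_subsets,
    select_extreme_trials,
    subset_t_test,
)


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "contrasts"
    out.mkdir(parents=True, exist_ok=True)
    meta = load_metadata(args.results)
    study = study_dir(args.results)
    scores = tio.read_table(
        args.results / "composites/composite_scores.tsv", index_col="trial_id"
    )
    group = tio.read_table(
        args.results / "networks/network_response_group.tsv", index_col="trial_id"
    )
    resid = tio.read_table(
        args.results / "associations/composite_scores_residualized.tsv",
        index_col="trial_id",
    )

    for comp, role, target in (
        ("Difficulty", None, "FPN-B"),
        ("SceneConstruction", "control", "DN-A"),
    ):
        spec = select_extreme_trials(scores, comp, 10, meta, role)
        rows = []
        for beta_path in sorted(study.glob("betas_*.tsv")):
            sid = beta_path.stem.replace("betas_", "")
            betas, trial_ids = tio.read_betas(beta_path)
            labels = tio.read_labels(study / f"labels_{sid}.tsv")
            cmap = compute_contrast_map(betas, trial_ids, spec, labels, target, sid)
            rows.append({"subject": sid, "target": target,
                         "mean_inside": cmap.mean_inside,
                         "mean_outside": cmap.mean_outside, "dice": cmap.dice})
        stats = pd.DataFrame(rows)
        tio.write_table(stats, out / f"contrast_overlap_{comp}.tsv")
        n_win = (stats["mean_inside"] > stats["mean_outside"]).sum()
        scope = f"{role} trials only" if role else "all trials"
        print(f"{comp} high-vs-low contrast ({scope}) vs {target} border: "
              f"inside > outside in {n_win}/{len(stats)} subjects, "
              f"median Dice {stats['dice'].median():.2f}")

    auto_side, scene_side = extreme_quadrant_subsets(
        resid, "Autobiographical", "SceneConstruction", 7, meta, role="control"
    )
    res = subset_t_test(
        group.loc[list(scene_side), "DN-A"].to_numpy(),
        group.loc[list(auto_side), "DN-A"].to_numpy(),
    )
    print(f"DN-A, Scene-leaning vs Autobiographical-leaning control subsets "
          f"(7 + 7 trials): Welch t({res.df:.2f}) = {res.t:.2f}, p = {res.p:.3g}")

    grid = tio.read_table(args.results / "associations/correlation_grid.tsv")
    table = dissociation_report(grid, ("SceneConstruction", "Difficulty"), ("DN-A", "FPN-B"))
    tio.write_table(table, out / "dissociation.tsv")
    verdict = "selective" if table.attrs["selective"] else "NOT selective"
    print(f"2x2 double dissociation ({verdict}):")
    print(table[["predictor", "network", "r", "ci_low", "ci_high"]].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
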