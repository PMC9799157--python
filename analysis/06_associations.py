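"""Relate composite scores to network responses: the full correlation grid
with Fisher CIs, per-network regressions with LMG relative importance and
VIFs, RT validation of the Difficulty composite, Difficulty residualization,
and the explainable-variance bookkeeping.
"""

from __future__ import annotations

import pandas as pd

from _common import load_kept_sessions, parse_args

from trialnet import io as tio
from trialnet.associations import (
    correlate_predictors_networks,
    fit_network_model,
    residualize_composites,
    rt_validation,
)
from trialnet.reliability import explainable_variance_fraction


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "associations"
    out.mkdir(parents=True, exist_ok=True)

    scores = tio.read_table(
        args.results / "composites/composite_scores.tsv", index_col="trial_id"
    )
    group = tio.read_table(
        args.results / "networks/network_response_group.tsv", index_col="trial_id"
    )

    grid = correlate_predictors_networks(scores, group)
    tio.write_table(grid, out / "correlation_grid.tsv")
    piv = grid.pivot(index="predictor", columns="network", values="r")
    print("composite x network correlations:")
    print(piv.round(2).to_string())

    model_cols = [c for c in ("Difficulty", "SceneConstruction", "OthersRelevant") if c in scores]
    rows = []
    for net in group.columns:
        fit = fit_network_model(group[net], scores[model_cols], net)
        for reg in fit.regressors:
            rows.append({"network": net, "regressor": reg, "coef": fit.coef[reg],
                         "p": fit.coef_p[reg], "lmg_r2": fit.lmg[reg],
                         "vif": fit.vif[reg], "r2_full": fit.r2, "f": fit.f,
                         "df1": fit.df1, "df2": fit.df2})
    models = pd.DataFrame(rows)
    tio.write_table(models, out / "network_models.tsv")

    rt_long = pd.concat(
        [s.trials[["trial_id", "response_time"]]
         for s in load_kept_sessions(args.results, "exp2")],
        ignore_index=True,
    )
    rt = rt_validation(rt_long, scores["Difficulty"])
    print(f"RT vs Difficulty: r = {rt.r:.2f}, CI [{rt.ci_low:.2f}, {rt.ci_high:.2f}], "
          f"p = {rt.p:.2g} (n = {rt.n} trials)")

    resid = residualize_composites(scores, "Difficulty")
    resid.to_csv(out / "composite_scores_residualized.tsv", sep="\t")
    resid_grid = correlate_predictors_networks(resid, group, residualized=True)
    tio.write_table(resid_grid, out / "correlation_grid_residualized.tsv")

    comp_rel = tio.read_table(
        args.results / "reliability/composite_split_half.tsv"
    ).set_index("composite")["adjusted_r"]
    net_rel = tio.read_table(
        args.results / "networks/network_split_half.tsv"
    ).set_index("network")["adjusted_r"]
    for comp, net in (("SceneConstruction", "DN-A"), ("Difficulty", "FPN-B")):
        lmg = models.query("network == @net and regressor == @comp")["lmg_r2"].iloc[0]
        ev = explainable_variance_fraction(lmg, comp_rel[comp], net_rel[net])
        print(f"{comp} -> {net}: R2 = {lmg:.2f} of ceiling {ev.ceiling:.2f} "
              f"= {100 * ev.fraction:.0f}% of explainable variance")


if __name__ == "__main__":
    main()
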