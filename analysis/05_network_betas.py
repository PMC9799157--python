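"""Aggregate per-subject trial betas into network responses: average betas
over each individually labeled network's vertices, then across subjects,
giving one response estimate per network per unique trial. Also estimates
network split-half reliability over subject halves (all 126 balanced splits
of 10 subjects).
"""

from __future__ import annotations

import pandas as pd

from _common import parse_args, study_dir

from trialnet import io as tio
from trialnet.glm import group_average, network_mean_response
from trialnet.reliability import split_half_reliability


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "networks"
    out.mkdir(parents=True, exist_ok=True)
    study = study_dir(args.results)

    responses = []
    for beta_path in sorted(study.glob("betas_*.tsv")):
        sid = beta_path.stem.replace("betas_", "")
        betas, trial_ids = tio.read_betas(beta_path)
        labels = tio.read_labels(study / f"labels_{sid}.tsv")
        responses.append(network_mean_response(betas, labels, trial_ids, sid))
    group = group_average(responses)
    group.values.to_csv(out / "network_response_group.tsv", sep="\t")
    print(f"group network response: {group.values.shape[0]} trials x "
          f"{group.values.shape[1]} networks from {len(responses)} subjects")

    rows = []
    for net in group.values.columns:
        table = pd.DataFrame(
            [r.values[net].to_numpy() for r in responses],
            index=[r.subjects[0] for r in responses],
        )
        est = split_half_reliability(table, scheme="all-combinations")
        rows.append({"network": net, "raw_r": est.raw_r, "adjusted_r": est.adjusted_r,
                     "n_splits": est.n_splits})
        print(f"split-half (SB-adjusted) {net}: r = {est.adjusted_r:.2f}")
    tio.write_table(pd.DataFrame(rows), out / "network_split_half.tsv")


if __name__ == "__main__":
    main()
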