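"""Render the synthetic study at the default study conditions and write every
raw table: rater sessions for both pseudo-experiments, trial metadata,
per-subject beta matrices and network labels, and the ground-truth latents.

All downstream analysis steps read only these files, mirroring a study where
the raw data arrive from outside.
"""

from __future__ import annotations

from _common import parse_args, study_dir

from trialnet import io as tio
from trialnet.config import GeneratorConfig
from trialnet.synthetic import simulate_study


def main() -> None:
    args = parse_args(__doc__)
    out = study_dir(args.results)
    out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(GeneratorConfig(seed=args.seed))
    tio.write_table(study.metadata, out / "trial_metadata.tsv")
    study.trial_latents.to_csv(out / "trial_latents_truth.tsv", sep="\t")
    tio.write_sessions(study.sessions_exp1, out / "sessions_exp1.tsv")
    tio.write_sessions(study.sessions_exp2, out / "sessions_exp2.tsv")
    trial_ids = study.metadata["trial_id"].to_numpy()
    for sid in sorted(study.betas):
        tio.write_betas(study.betas[sid], trial_ids, out / f"betas_{sid}.tsv")
        tio.write_labels(study.labels[sid], out / f"labels_{sid}.tsv")
    n_contam = len(study.truth_types)
    n_sessions = len(study.sessions_exp1) + len(study.sessions_exp2)
    print(f"wrote study to {out}")
    print(
        f"  {n_sessions} rater sessions ({n_contam} contaminated), "
        f"{len(study.betas)} scanned subjects, "
        f"{study.config.n_vertices} vertices, {study.config.n_trials} trials"
    )


if __name__ == "__main__":
    main()
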