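"""Apply the exclusion rules to both rater samples and run the cohort check.

Writes the per-rater exclusion ledger and the per-cohort summary (mirroring
the published summary-table layout), and reports the cohort-effect ANOVA on
the trials shared by all raters.
"""

from __future__ import annotations

from _common import load_metadata, load_sessions, parse_args

from trialnet import io as tio
from trialnet.qc import apply_exclusions, cohort_effect_test, kept_sessions


def main() -> None:
    args = parse_args(__doc__)
    out = args.results / "qc"
    out.mkdir(parents=True, exist_ok=True)
    meta = load_metadata(args.results)
    shared = meta["trial_id"].head(6).tolist()

    for label in ("exp1", "exp2"):
        sessions = load_sessions(args.results, label)
        report = apply_exclusions(sessions)
        tio.write_table(report.per_rater, out / f"exclusion_ledger_{label}.tsv")
        tio.write_table(report.cohort_summary, out / f"exclusion_summary_{label}.tsv")
        kept = kept_sessions(sessions, report)
        test = cohort_effect_test(kept, shared)
        overall = report.cohort_summary.iloc[-1]
        print(
            f"{label}: kept {overall['n_included']}/{overall['n_enrolled']} raters "
            f"({overall['pct_included']:.1f}%); "
            f"cohort effect F({test.df1},{test.df2}) = {test.f:.2f}, p = {test.p:.2f}"
        )
    print(f"ledgers written to {out}")


if __name__ == "__main__":
    main()
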