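"""Published summary tables of the two online rating experiments.

These are the per-cohort enrollment/exclusion ledgers and the per-probe
summary column (mean, SD, inter-experiment reliability) as printed with the
original studies. They serve as worked-example inputs: overall retention,
demographic summaries and the reliability-column minimum are recomputed from
the cohort cells rather than asserted.

The ``exc_other`` column covers the one exclusion reported outside the rule
columns (a second-experiment cohort-5 participant excluded for aphantasia),
so that enrolled = included + sum(exclusions) holds in every row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_EXCLUSION_COLUMNS = (
    "exc_time",
    "exc_clicks",
    "exc_checks",
    "exc_patterned",
    "exc_age",
    "exc_other",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("trialnet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def exclusion_summary(experiment: int) -> pd.DataFrame:
    """Per-cohort enrollment and exclusion tallies for experiment 1 or 2."""
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    return _load(f"exclusion_summary_exp{experiment}.tsv")


def strategy_probe_summary() -> pd.DataFrame:
    """Per-probe mean rating, SD and inter-experiment reliability."""
    return _load("strategy_probes.tsv").set_index("strategy")


def recompute_overall(summary: pd.DataFrame) -> dict[str, float]:
    """Recompute study-level quantities from the cohort cells: totals per
    exclusion rule, retention percentage, included-weighted mean age, and
    percent female."""
    n_enrolled = int(summary["n_enrolled"].sum())
    n_included = int(summary["n_included"].sum())
    out: dict[str, float] = {
        "n_enrolled": n_enrolled,
        "n_included": n_included,
        "pct_included": 100.0 * n_included / n_enrolled,
        "mean_age": float(
            (summary["mean_age"] * summary["n_included"]).sum() / n_included
        ),
        "n_female": int(summary["n_female"].sum()),
        "pct_female": 100.0 * summary["n_female"].sum() / n_included,
    }
    for col in _EXCLUSION_COLUMNS:
        out[col] = int(summary[col].sum())
    balance = summary["n_included"] + summary[list(_EXCLUSION_COLUMNS)].sum(axis=1)
    out["tallies_conserved"] = bool((balance == summary["n_enrolled"]).all())
    return out
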