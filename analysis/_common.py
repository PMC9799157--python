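"""Shared plumbing for the numbered analysis drivers: canonical result paths
and re-loading of intermediates written by earlier steps."""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from trialnet import io as tio

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
STUDY = RESULTS / "study"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results", type=Path, default=RESULTS)
    return parser.parse_args()


def study_dir(results: Path) -> Path:
    return results / "study"


def load_metadata(results: Path) -> pd.DataFrame:
    return tio.read_table(study_dir(results) / "trial_metadata.tsv")


def load_sessions(results: Path, experiment: str):
    return tio.read_sessions(study_dir(results) / f"sessions_{experiment}.tsv")


def load_kept_sessions(results: Path, experiment: str):
    sessions = load_sessions(results, experiment)
    ledger = tio.read_table(results / f"qc/exclusion_ledger_{experiment}.tsv")
    kept = set(ledger.loc[ledger["kept"], "rater_id"])
    return [s for s in sessions if s.rater_id in kept]
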