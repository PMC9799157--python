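"""Plain-text interchange: TSV for tables and matrices, YAML/JSON for records.

TSV is the canonical format at this data scale because every intermediate can
be inspected at a desk. Beta matrices are written one file per subject with a
trial_id index column; labels are two-column (vertex_index, network).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import NETWORKS, RATING_MAX, RATING_MIN, STRATEGIES
from .sessions import RaterSession, frame_to_sessions, sessions_to_frame


def write_sessions(sessions: list[RaterSession], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def read_sessions(path: str | Path) -> list[RaterSession]:
    return frame_to_sessions(pd.read_csv(path, sep="\t"))


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_betas(betas: np.ndarray, trial_ids: np.ndarray, path: str | Path) -> None:
    frame = pd.DataFrame(betas, index=pd.Index(trial_ids, name="trial_id"))
    frame.to_csv(path, sep="\t")


def read_betas(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col="trial_id")
    return frame.to_numpy(dtype=float), frame.index.to_numpy()


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"vertex_index": np.arange(len(labels)), "network": labels}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t")
    return frame.sort_values("vertex_index")["network"].to_numpy(dtype=object)


def write_yaml(record: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(record, sort_keys=True))


def write_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# schema validation for external inputs


def validate_session_frame(frame: pd.DataFrame) -> list[str]:
    """Fatal schema problems in a long session table (empty list = valid)."""
    errors: list[str] = []
    required = {"rater_id", "cohort", "age", "duration_min", "trial_id", *STRATEGIES}
    missing = required - set(frame.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    ratings = frame[list(STRATEGIES)]
    if ((ratings < RATING_MIN) | (ratings > RATING_MAX)).any().any():
        errors.append(f"rating values outside [{RATING_MIN},{RATING_MAX}]")
    if (frame["duration_min"] < 0).any():
        errors.append("negative survey durations")
    dup = frame.duplicated(["rater_id", "trial_id"])
    if dup.any():
        errors.append("duplicate (rater_id, trial_id) rows")
    return errors


def validate_labels_frame(frame: pd.DataFrame) -> list[str]:
    errors: list[str] = []
    if not {"vertex_index", "network"} <= set(frame.columns):
        return ["labels file needs vertex_index and network columns"]
    unknown = set(frame["network"]) - set(NETWORKS) - {"unassigned"}
    if unknown:
        errors.append(f"unknown network names: {sorted(unknown)}")
    if frame["vertex_index"].duplicated().any():
        errors.append("duplicate vertex indices")
    return errors


def validate_beta_trials(
    beta_trial_ids: np.ndarray, metadata: pd.DataFrame
) -> list[str]:
    dangling = set(beta_trial_ids) - set(metadata["trial_id"])
    if dangling:
        return [f"beta trials missing from metadata: {sorted(dangling)[:5]}"]
    return []
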