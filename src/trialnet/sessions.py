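"""Rater-session container and tidy-frame conversions."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import RATING_MAX, RATING_MIN, STRATEGIES

#: rater-level columns stored alongside every trial row in the long format
SESSION_COLUMNS = ["rater_id", "cohort", "age", "duration_min"]
TRIAL_COLUMNS = ["trial_id", "answer", "response_time", "click_count"]
CHECK_NAMES = ("focus", "pets", "reading")


@dataclass
class RaterSession:
    """One online rater's survey: demographics, per-trial answers and the
    16 strategy ratings, plus compliance-check outcomes.

    ``trials`` has one row per administered trial with columns
    ``trial_id, answer, response_time, click_count`` and one column per
    strategy probe.
    """

    rater_id: str
    cohort: str
    age: float
    duration_min: float
    trials: pd.DataFrame
    check_outcomes: dict[str, bool] = field(
        default_factory=lambda: {c: True for c in CHECK_NAMES}
    )
    feedback_ok: bool = True
    truth_type: str | None = None  # generator ground truth; None for real data

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS + list(STRATEGIES) if c not in self.trials]
        if missing:
            raise ValueError(f"session {self.rater_id} missing columns: {missing}")
        if self.duration_min < 0:
            raise ValueError("duration must be nonnegative")
        if self.trials["trial_id"].duplicated().any():
            raise ValueError(f"duplicate trial ids in session {self.rater_id}")
        ratings = self.trials[list(STRATEGIES)]
        if ((ratings < RATING_MIN) | (ratings > RATING_MAX)).any().any():
            raise ValueError(f"ratings outside [1,7] in session {self.rater_id}")

    @property
    def n_checks_missed(self) -> int:
        return sum(not ok for ok in self.check_outcomes.values())

    def ratings(self) -> pd.DataFrame:
        """Trial-indexed 16-column rating block, in canonical strategy order."""
        return self.trials.set_index("trial_id")[list(STRATEGIES)]


def sessions_to_frame(sessions: list[RaterSession]) -> pd.DataFrame:
    """Long/tidy frame: one row per rater x trial, rater fields repeated."""
    parts = []
    for s in sessions:
        block = s.trials.copy()
        block.insert(0, "rater_id", s.rater_id)
        block.insert(1, "cohort", s.cohort)
        block.insert(2, "age", s.age)
        block.insert(3, "duration_min", s.duration_min)
        for name in CHECK_NAMES:
            block[f"check_{name}"] = s.check_outcomes[name]
        block["feedback_ok"] = s.feedback_ok
        block["truth_type"] = s.truth_type if s.truth_type is not None else "none"
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


def frame_to_sessions(frame: pd.DataFrame) -> list[RaterSession]:
    sessions = []
    for rater_id, block in frame.groupby("rater_id", sort=False):
        first = block.iloc[0]
        truth = first.get("truth_type", "none")
        sessions.append(
            RaterSession(
                rater_id=str(rater_id),
                cohort=str(first["cohort"]),
                age=float(first["age"]),
                duration_min=float(first["duration_min"]),
                trials=block[TRIAL_COLUMNS + list(STRATEGIES)].reset_index(drop=True),
                check_outcomes={
                    name: bool(first[f"check_{name}"]) for name in CHECK_NAMES
                },
                feedback_ok=bool(first.get("feedback_ok", True)),
                truth_type=None if truth == "none" else str(truth),
            )
        )
    return sessions
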