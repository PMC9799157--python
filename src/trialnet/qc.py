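"""Participant-level quality control for online rating sessions.

Implements the study's exclusion rules (age range, survey duration, zero-click
trials, missed compliance checks, patterned responding), an algorithmic
replacement for the human patterned-responding review, and the cohort-effect
check run on the trials shared by all raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import VISUALIZED_STRATEGIES
from .sessions import RaterSession

#: exclusion precedence: age is applied first, then the tally columns left to right
REASON_ORDER = ("age", "time", "clicks", "checks", "patterned")


@dataclass
class PatternParams:
    """Thresholds for the three stereotyped-responding rules.

    theta_const: flag when at least this fraction of trials has zero
        within-trial rating variance (straight-liners).
    theta_rep: flag when one exact rating sequence recurs on at least this
        fraction of trials (stereotyped cycles).
    q_late / early_const_max: flag a performance drop-off when the trailing
        run of within-trial-constant trials covers at least ``q_late`` of the
        survey while the trials before it are mostly non-constant.
    """

    theta_const: float = 0.8
    theta_rep: float = 0.8
    q_late: float = 0.2
    early_const_max: float = 0.2
    min_trials: int = 5
    strategies: tuple[str, ...] = VISUALIZED_STRATEGIES


@dataclass
class QCCriteria:
    age_range: tuple[float, float] = (18.0, 28.0)
    min_duration_min: float = 20.0  # duration <= threshold is excluded
    max_zero_click_trials: int = 1  # more than this many zero-click trials excludes
    max_missed_checks: int = 1
    pattern: PatternParams = field(default_factory=PatternParams)


@dataclass
class ExclusionReport:
    per_rater: pd.DataFrame  # rater_id, cohort, kept, reason, flags
    cohort_summary: pd.DataFrame  # tallies mirroring the published summary tables

    def kept_ids(self) -> list[str]:
        return self.per_rater.loc[self.per_rater["kept"], "rater_id"].tolist()


@dataclass
class CohortTestResult:
    f: float
    df1: int
    df2: int
    p: float
    description: str


def detect_patterned_responses(
    session: RaterSession, params: PatternParams | None = None
) -> tuple[bool, list[str]]:
    """Flag stereotyped responding; returns (flag, list of rules triggered)."""
    params = params or PatternParams()
    ratings = session.trials[list(params.strategies)].to_numpy(dtype=float)
    n = ratings.shape[0]
    if n < params.min_trials:
        raise ValueError(
            f"session {session.rater_id}: {n} trials < min_trials={params.min_trials}"
        )
    constant = np.ptp(ratings, axis=1) == 0
    evidence: list[str] = []
    if constant.mean() >= params.theta_const:
        evidence.append("constant_within_trial")

    _, counts = np.unique(ratings, axis=0, return_counts=True)
    if counts.max() / n >= params.theta_rep:
        evidence.append("repeated_sequence")

    suffix = 0  # trailing run of within-trial-constant trials
    while suffix < n and constant[n - 1 - suffix]:
        suffix += 1
    head = constant[: n - suffix]
    if (
        head.size
        and suffix / n >= params.q_late
        and head.mean() <= params.early_const_max
    ):
        evidence.append("late_dropoff")
    return bool(evidence), evidence


def _classify(session: RaterSession, criteria: QCCriteria) -> tuple[str, list[str]]:
    """Return (reason, flags); reason 'none' when the session is kept."""
    lo, hi = criteria.age_range
    if not lo <= session.age <= hi:
        return "age", []
    if session.duration_min <= criteria.min_duration_min:
        return "time", []
    zero_click = int((session.trials["click_count"] == 0).sum())
    if zero_click > criteria.max_zero_click_trials:
        return "clicks", []
    if session.n_checks_missed > criteria.max_missed_checks:
        return "checks", []
    patterned, evidence = detect_patterned_responses(session, criteria.pattern)
    if patterned:
        return "patterned", evidence
    flags = []
    if session.n_checks_missed == 1:
        flags.append("missed_one_check")
    if not session.feedback_ok:
        flags.append("feedback_missing")
    if zero_click == criteria.max_zero_click_trials and zero_click > 0:
        flags.append("zero_click_trial")
    return "none", flags


def apply_exclusions(
    sessions: list[RaterSession], criteria: QCCriteria | None = None
) -> ExclusionReport:
    """Apply all exclusion rules with the fixed reason precedence.

    A session receives exactly one reason (the first applicable in
    age > time > clicks > checks > patterned order); single soft infractions
    are recorded as flags without excluding.
    """
    criteria = criteria or QCCriteria()
    rows = []
    for s in sessions:
        reason, notes = _classify(s, criteria)
        rows.append(
            {
                "rater_id": s.rater_id,
                "cohort": s.cohort,
                "age": s.age,
                "kept": reason == "none",
                "reason": reason,
                "flags": ";".join(notes),
            }
        )
    per_rater = pd.DataFrame(rows).sort_values("rater_id", ignore_index=True)

    summaries = []
    groups = [(c, g) for c, g in per_rater.groupby("cohort")]
    groups.append(("overall", per_rater))
    for name, g in groups:
        kept = g[g["kept"]]
        row = {"cohort": name, "n_enrolled": len(g)}
        for reason in ("time", "clicks", "checks", "patterned", "age"):
            row[f"exc_{reason}"] = int((g["reason"] == reason).sum())
        row["n_included"] = len(kept)
        row["pct_included"] = 100.0 * len(kept) / len(g) if len(g) else float("nan")
        row["mean_age"] = kept["age"].mean() if len(kept) else float("nan")
        summaries.append(row)
    report = ExclusionReport(per_rater=per_rater, cohort_summary=pd.DataFrame(summaries))

    # tally conservation, by construction but asserted defensively
    cs = report.cohort_summary
    total = cs[[c for c in cs.columns if c.startswith("exc_")]].sum(axis=1) + cs["n_included"]
    assert (total == cs["n_enrolled"]).all()
    return report


def kept_sessions(
    sessions: list[RaterSession], report: ExclusionReport
) -> list[RaterSession]:
    kept = set(report.kept_ids())
    return [s for s in sessions if s.rater_id in kept]


def cohort_effect_test(
    sessions: list[RaterSession],
    shared_trial_ids: list[int],
    strategies: tuple[str, ...] = VISUALIZED_STRATEGIES,
) -> CohortTestResult:
    """One-way ANOVA of per-participant mean ratings (over the shared trials
    and the visualized strategies) on cohort."""
    shared = set(shared_trial_ids)
    means: dict[str, list[float]] = {}
    for s in sessions:
        block = s.trials[s.trials["trial_id"].isin(shared)]
        if set(block["trial_id"]) != shared:
            raise ValueError(
                f"session {s.rater_id} did not rate every shared trial"
            )
        means.setdefault(s.cohort, []).append(
            float(block[list(strategies)].to_numpy().mean())
        )
    groups = [np.asarray(v) for _, v in sorted(means.items())]
    result = cohort_anova(groups)
    result.description = (
        "one-way ANOVA of participant mean rating "
        f"({len(shared)} shared trials x {len(strategies)} probes) on cohort"
    )
    return result


def cohort_anova(groups: list[np.ndarray]) -> CohortTestResult:
    """One-way ANOVA over per-participant summary values grouped by cohort."""
    if len(groups) < 2:
        raise ValueError("cohort effect test needs at least 2 cohorts")
    f, p = stats.f_oneway(*groups)
    return CohortTestResult(
        f=float(f),
        df1=len(groups) - 1,
        df2=sum(len(g) for g in groups) - len(groups),
        p=float(p),
        description="one-way ANOVA on cohort",
    )
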