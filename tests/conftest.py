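"""Shared fixtures: hand-built sessions, a small synthetic study, and a
full-size default study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialnet.config import GeneratorConfig
from trialnet.constants import CONDITIONS, STRATEGIES
from trialnet.sessions import RaterSession
from trialnet.synthetic import simulate_study


def make_session(
    rater_id: str = "r1",
    cohort: str = "c1",
    age: float = 22.0,
    duration_min: float = 45.0,
    ratings: np.ndarray | None = None,
    n_trials: int = 12,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> RaterSession:
    """Compliant session with random (or supplied) integer ratings."""
    rng = rng or np.random.default_rng(0)
    if ratings is None:
        ratings = rng.integers(1, 8, (n_trials, len(STRATEGIES))).astype(float)
    n_trials = ratings.shape[0]
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(1, n_trials + 1),
            "answer": rng.integers(1, 4, n_trials),
            "response_time": rng.uniform(5, 15, n_trials),
            "click_count": rng.poisson(2, n_trials) + 1,
        }
    )
    trials[list(STRATEGIES)] = ratings
    return RaterSession(
        rater_id=rater_id,
        cohort=cohort,
        age=age,
        duration_min=duration_min,
        trials=trials,
        **kwargs,
    )


def small_generator_config(seed: int = 7, **overrides) -> GeneratorConfig:
    base = dict(
        n_trials=60,
        conditions={c: 10 for c in CONDITIONS},
        n_raters_per_trial=(8, 12),
        trials_per_cohort=30,
        n_subjects=4,
        n_vertices=120,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_generator_config())


@pytest.fixture(scope="session")
def default_study():
    """Full-size study at the default (study-condition) configuration."""
    return simulate_study(GeneratorConfig(seed=11))
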