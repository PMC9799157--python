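"""Generator configuration: the generative model behind every synthetic study.

The generative story is a latent-factor measurement model. Each trial t carries a
vector of latent processing demands f_t (one per composite-level factor). Raters
observe noisy Likert renderings of strategy-specific linear combinations
``mu_s + Lambda[s] @ f_t``; cortical networks respond with
``W[n] @ f_t`` plus trial-, subject- and vertex-level noise. Because the same
latents drive ratings and responses, the downstream composite-network correlation
grid has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    CANONICAL_COMPOSITES,
    CONDITIONS,
    CONTROL_CONDITIONS,
    FACTORS,
    NETWORKS,
    STRATEGIES,
)


def default_loading_matrix() -> pd.DataFrame:
    """Strategy loadings Lambda (16 strategies x 5 factors).

    Composite members load on their own factor, with the Difficulty pair
    (Facts, Difficulty) loading more weakly than the rest: that makes it the
    loosest surviving cluster, so a dendrogram cut at its merge height keeps
    exactly the five composite groups. The four probes excluded from
    canonical composites get split or weak loadings, which makes their
    cluster attachment weak and unstable between replications.
    """
    lam = pd.DataFrame(0.0, index=list(STRATEGIES), columns=list(FACTORS))
    for factor, members in CANONICAL_COMPOSITES.items():
        for s in members:
            lam.loc[s, factor] = 0.85 if factor == "Difficulty" else 1.1
    lam.loc["Relationships", ["OthersRelevant", "SelfRelevant"]] = 0.5
    lam.loc["Loc_People", ["SceneConstruction", "OthersRelevant"]] = 0.5
    lam.loc["Moral_Principles", "OthersRelevant"] = 0.3
    lam.loc["Specificity", ["SceneConstruction", "Autobiographical", "SelfRelevant"]] = 0.35
    return lam


def default_network_loading() -> pd.DataFrame:
    """Network loadings W (6 networks x 5 factors): the selectivity ground truth."""
    w = pd.DataFrame(0.0, index=list(NETWORKS), columns=list(FACTORS))
    w.loc["DN-A", "SceneConstruction"] = 1.0
    w.loc["FPN-B", "Difficulty"] = 1.0
    w.loc["FPN-A", "Difficulty"] = 0.6
    w.loc["DN-B", "OthersRelevant"] = 0.35
    return w


def default_network_trial_noise_sd() -> dict[str, float]:
    """Trial-level network noise sigma_n, shared over subjects and vertices.

    Chosen from r = a / sqrt(a^2 + sigma^2 + s^2/n_subjects) at unit factor
    variance (a = network loading, s = subject-level trial noise sd) so the
    group-level factor-network correlations sit near 0.6 (DN-A), 0.7 (FPN-B),
    0.5 (FPN-A) and 0.3 (DN-B).
    """
    return {
        "DN-A": 1.206,
        "DN-B": 0.956,
        "LANG": 1.0,
        "FPN-A": 0.869,
        "FPN-B": 0.847,
        "CING-OPER": 1.0,
    }


def default_factor_cov() -> pd.DataFrame:
    """Factor correlation matrix; Difficulty correlates 0.5 with the two
    composites it confounds, so residualization has something to remove."""
    cov = pd.DataFrame(np.eye(len(FACTORS)), index=list(FACTORS), columns=list(FACTORS))
    for other in ("SelfRelevant", "Autobiographical"):
        cov.loc["Difficulty", other] = cov.loc[other, "Difficulty"] = 0.5
    return cov


def default_condition_shift() -> dict[str, dict[str, float]]:
    """Per-condition latent mean offsets: target trials demand more scene
    construction and autobiographical processing, by design of the task."""
    shift: dict[str, dict[str, float]] = {}
    for cond in CONDITIONS:
        if cond not in CONTROL_CONDITIONS:
            shift[cond] = {"SceneConstruction": 0.7, "Autobiographical": 1.0}
    return shift


@dataclass
class RTLink:
    """Response time model: rt = intercept + slope * Difficulty_t +
    trial_effect_t + noise, floored at ``floor`` seconds; a small rate of
    >60 s outliers.

    ``trial_noise_sd`` is idiosyncratic per-trial slowness shared by all
    raters (question length, answer-option ambiguity); it does not average
    away over raters, which is what keeps the trial-mean RT vs Difficulty
    correlation near the mid-0.6s rather than 1. With slope 1.5 on a
    unit-variance latent, sd 1.75 puts it at 1.5/sqrt(1.5^2+1.75^2) ~ 0.65.
    """

    intercept: float = 9.0
    slope: float = 1.5
    trial_noise_sd: float = 1.75
    noise_sd: float = 3.0
    outlier_rate: float = 0.0017
    floor: float = 0.5


@dataclass
class GeneratorConfig:
    n_trials: int = 180
    conditions: dict[str, int] = field(
        default_factory=lambda: {c: 30 for c in CONDITIONS}
    )
    control_roles: frozenset[str] = CONTROL_CONDITIONS
    n_raters_per_trial: tuple[int, int] = (25, 50)
    trials_per_cohort: int = 30
    n_shared_trials: int = 6
    n_subjects: int = 10
    n_vertices: int = 600
    factor_names: tuple[str, ...] = FACTORS
    loading_matrix: pd.DataFrame = field(default_factory=default_loading_matrix)
    baseline_mean: float = 3.5
    condition_shift: dict[str, dict[str, float]] = field(
        default_factory=default_condition_shift
    )
    factor_cov: pd.DataFrame = field(default_factory=default_factor_cov)
    network_loading: pd.DataFrame = field(default_factory=default_network_loading)
    network_trial_noise_sd: dict[str, float] = field(
        default_factory=default_network_trial_noise_sd
    )
    rating_noise_sd: float = 1.2
    rater_bias_sd: float = 0.5
    network_noise_sd: float = 0.5
    subject_noise_sd: float = 0.3
    #: per-subject per-trial network response noise; sets the network
    #: split-half reliability (~0.85-0.9 over 10 subjects at the default)
    subject_trial_noise_sd: float = 1.8
    contamination: dict[str, float] = field(
        default_factory=lambda: {
            "straight_liner": 0.05,
            "cyclic": 0.04,
            "late_dropoff": 0.03,
            "under_time": 0.07,
            "out_of_age": 0.01,
        }
    )
    rt_link: RTLink = field(default_factory=RTLink)
    discretize: bool = True
    seed: int = 0

    CONTAMINATION_TYPES = (
        "straight_liner",
        "cyclic",
        "late_dropoff",
        "under_time",
        "out_of_age",
    )

    def validate(self) -> None:
        if self.n_trials <= 0 or self.n_subjects <= 0 or self.n_vertices <= 0:
            raise ValueError("counts must be positive")
        if sum(self.conditions.values()) != self.n_trials:
            raise ValueError("condition trial counts must sum to n_trials")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if not self.control_roles <= set(self.conditions):
            raise ValueError("control_roles must be a subset of the conditions")
        if any(n < 1 for n in self.n_raters_per_trial):
            raise ValueError("rater count < 1 for a pseudo-experiment")
        for name, sd in (
            ("rating_noise_sd", self.rating_noise_sd),
            ("rater_bias_sd", self.rater_bias_sd),
            ("network_noise_sd", self.network_noise_sd),
            ("subject_noise_sd", self.subject_noise_sd),
            ("subject_trial_noise_sd", self.subject_trial_noise_sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be nonnegative")
        rates = self.contamination
        if set(rates) - set(self.CONTAMINATION_TYPES):
            raise ValueError("unknown contamination type")
        if any(not 0.0 <= r <= 1.0 for r in rates.values()) or sum(rates.values()) > 1.0:
            raise ValueError("contamination rates must lie in [0,1] and sum to <= 1")
        if list(self.loading_matrix.index) != list(STRATEGIES):
            raise ValueError("loading_matrix rows must be the 16 canonical strategies")
        if list(self.loading_matrix.columns) != list(self.factor_names):
            raise ValueError("loading_matrix columns must match factor_names")
        if list(self.network_loading.columns) != list(self.factor_names):
            raise ValueError("network_loading columns must match factor_names")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)
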