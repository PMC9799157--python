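"""Synthetic-study generator with known ground truth.

Every rendered quantity descends from the per-trial latent factor matrix, so
parameter-recovery tests can score each analysis stage against the truth:
ratings are noisy Likert renderings of ``mu + Lambda f``, response times follow
the Difficulty latent, and network responses follow ``W f`` plus trial-,
subject- and vertex-level noise. Contaminated raters (straight-liners, cyclic
patterns, late drop-off, under-time, out-of-age) are injected at configured
rates with their type recorded, so the QC detectors can be scored for
sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .constants import CONDITIONS, RATING_MAX, RATING_MIN, STRATEGIES
from .sessions import RaterSession

_CYCLIC_BASE = (1, 2, 3, 4, 3, 2, 1, 2, 3, 4)


def trial_metadata(config: GeneratorConfig) -> pd.DataFrame:
    """Trial table: id, condition, target/control role.

    Conditions are interleaved so that every block of ``trials_per_cohort``
    consecutive trials contains an equal mix of conditions (mirroring runs
    that present five trials per condition).
    """
    config.validate()
    labels: list[str] = []
    remaining = dict(config.conditions)
    order = [c for c in CONDITIONS if c in remaining]
    while len(labels) < config.n_trials:
        for cond in order:
            if remaining[cond] > 0:
                labels.append(cond)
                remaining[cond] -= 1
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(1, config.n_trials + 1),
            "condition": labels,
            "role": [
                "control" if c in config.control_roles else "target" for c in labels
            ],
        }
    )
    return meta


def sample_trial_latents(
    config: GeneratorConfig,
    metadata: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trials x factors latent matrix: standard-normal columns (with the
    configured factor correlations) plus per-condition mean shifts."""
    config.validate()
    if metadata is None:
        metadata = trial_metadata(config)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    factors = list(config.factor_names)
    chol = np.linalg.cholesky(config.factor_cov.loc[factors, factors].to_numpy())
    z = rng.standard_normal((config.n_trials, len(factors))) @ chol.T
    latents = pd.DataFrame(z, index=metadata["trial_id"].to_numpy(), columns=factors)
    latents.index.name = "trial_id"
    for cond, shifts in config.condition_shift.items():
        if cond not in config.conditions:
            raise ValueError(f"unknown condition label in condition_shift: {cond}")
        mask = (metadata["condition"] == cond).to_numpy()
        for factor, delta in shifts.items():
            latents.loc[mask, factor] += delta
    return latents


def _cohort_trial_ids(config: GeneratorConfig, metadata: pd.DataFrame):
    """Split trials into cohort blocks plus a shared set rated by everyone."""
    ids = metadata["trial_id"].to_numpy()
    shared = ids[: config.n_shared_trials]
    blocks = [
        ids[i : i + config.trials_per_cohort]
        for i in range(0, len(ids), config.trials_per_cohort)
    ]
    return shared, blocks


def render_rts(
    latents: pd.DataFrame,
    config: GeneratorConfig,
    trial_ids: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial response times for one session (seconds).

    The idiosyncratic per-trial effect is redrawn deterministically from the
    study seed so every session shares it (it is a trial property, not a
    rater one)."""
    link = config.rt_link
    diff = latents.loc[trial_ids, "Difficulty"].to_numpy()
    trial_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7271]))
    effects = pd.Series(
        trial_rng.normal(0.0, link.trial_noise_sd, len(latents)), index=latents.index
    )
    rt = (
        link.intercept
        + link.slope * diff
        + effects.loc[trial_ids].to_numpy()
        + rng.normal(0.0, link.noise_sd, len(diff))
    )
    rt = np.maximum(rt, link.floor)
    if np.all(rt <= 0):
        raise ValueError("rt link produced no positive response times")
    outliers = rng.random(len(rt)) < link.outlier_rate
    rt[outliers] = rng.uniform(61.0, 120.0, outliers.sum())
    return rt


def _compliant_ratings(
    latents: pd.DataFrame,
    config: GeneratorConfig,
    trial_ids: np.ndarray,
    bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = config.loading_matrix.to_numpy()  # strategies x factors
    f = latents.loc[trial_ids, list(config.factor_names)].to_numpy()
    x = config.baseline_mean + f @ lam.T + bias
    x = x + rng.normal(0.0, config.rating_noise_sd, x.shape)
    if config.discretize:
        x = np.round(x)
    return np.clip(x, RATING_MIN, RATING_MAX)


def _contaminated_ratings(
    kind: str,
    base: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_trials, n_strat = base.shape
    out = base.copy()
    if kind == "straight_liner":
        values = rng.integers(RATING_MIN, RATING_MAX + 1, n_trials)
        out = np.repeat(values[:, None], n_strat, axis=1).astype(float)
    elif kind == "cyclic":
        pattern = np.resize(np.array(_CYCLIC_BASE, dtype=float), n_strat)
        out = np.tile(pattern, (n_trials, 1))
    elif kind == "late_dropoff":
        cut = int(round(rng.uniform(0.5, 0.7) * n_trials))
        values = rng.integers(RATING_MIN, RATING_MAX + 1, n_trials - cut)
        out[cut:] = np.repeat(values[:, None], n_strat, axis=1)
    return out


def render_rating_sessions(
    latents: pd.DataFrame,
    config: GeneratorConfig,
    metadata: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[RaterSession], list[RaterSession]]:
    """Render rater sessions for both pseudo-experiments.

    Each cohort of raters rates its own block of trials plus the shared
    trials; contaminated raters are injected at the configured rates with
    their type recorded on the session.
    """
    config.validate()
    if (config.loading_matrix.to_numpy() != 0).sum() == 0 and config.rating_noise_sd:
        pass  # all-zero loadings are legal: pure-noise ratings
    if metadata is None:
        metadata = trial_metadata(config)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    shared, blocks = _cohort_trial_ids(config, metadata)
    types = list(config.CONTAMINATION_TYPES)
    rates = np.array([config.contamination.get(t, 0.0) for t in types])
    cum = np.cumsum(rates)

    experiments: list[list[RaterSession]] = []
    for exp_idx, n_raters in enumerate(config.n_raters_per_trial):
        if n_raters < 1:
            raise ValueError("rater count < 1 for a pseudo-experiment")
        sessions: list[RaterSession] = []
        for cohort_idx, block in enumerate(blocks):
            trial_ids = np.concatenate([shared, block[~np.isin(block, shared)]])
            for r in range(n_raters):
                u = rng.random()
                hit = np.searchsorted(cum, u)
                kind = types[hit] if hit < len(types) and u < cum[-1] else None

                age = float(rng.integers(18, 27))
                duration = float(max(21.0, rng.normal(45.0, 8.0)))
                if kind == "out_of_age":
                    age = float(rng.integers(29, 41))
                elif kind == "under_time":
                    duration = float(rng.uniform(5.0, 19.5))

                bias = rng.normal(0.0, config.rater_bias_sd)
                ratings = _compliant_ratings(latents, config, trial_ids, bias, rng)
                if kind in ("straight_liner", "cyclic", "late_dropoff"):
                    ratings = _contaminated_ratings(kind, ratings, rng)

                trials = pd.DataFrame(
                    {
                        "trial_id": trial_ids,
                        "answer": rng.integers(1, 4, len(trial_ids)),
                        "response_time": render_rts(latents, config, trial_ids, rng),
                        "click_count": rng.poisson(1.5, len(trial_ids)) + 1,
                    }
                )
                trials[list(STRATEGIES)] = ratings
                sessions.append(
                    RaterSession(
                        rater_id=f"e{exp_idx + 1}_c{cohort_idx + 1}_r{r + 1:03d}",
                        cohort=f"c{cohort_idx + 1}",
                        age=age,
                        duration_min=duration,
                        trials=trials,
                        truth_type=kind,
                    )
                )
        experiments.append(sessions)
    return experiments[0], experiments[1]


def render_network_responses(
    latents: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], pd.DataFrame]:
    """Per-subject trial x vertex beta matrices plus vertex network labels.

    ``beta[t, v] = W[net(v)] @ f_t + eta[net(v), t] + subject_offset + eps``
    where ``eta`` is trial-level network noise shared across subjects (true
    response variance not explained by the behavioral factors).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    networks = list(config.network_loading.index)
    f = latents[list(config.factor_names)].to_numpy()
    w = config.network_loading.to_numpy()
    signal = f @ w.T  # trials x networks
    eta_sd = np.array([config.network_trial_noise_sd.get(n, 0.0) for n in networks])
    eta = rng.normal(0.0, 1.0, signal.shape) * eta_sd
    network_response = signal + eta

    n_v = config.n_vertices
    base_bounds = np.linspace(0, n_v, len(networks) + 1).astype(int)
    jitter = max(1, n_v // 120)

    betas: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        bounds = base_bounds.copy()
        if jitter and n_v >= 2 * len(networks):
            bounds[1:-1] = bounds[1:-1] + rng.integers(-jitter, jitter + 1, len(networks) - 1)
            bounds = np.maximum.accumulate(bounds)
        label = np.empty(n_v, dtype=object)
        for i, net in enumerate(networks):
            label[bounds[i] : bounds[i + 1]] = net
        if (label == None).any():  # noqa: E711 - object array fill check
            raise ValueError("vertex without a network label")
        net_index = np.searchsorted(bounds[1:], np.arange(n_v), side="right")
        offsets = rng.normal(0.0, config.subject_noise_sd, len(networks))
        subject_trial = rng.normal(
            0.0, config.subject_trial_noise_sd, (len(latents), len(networks))
        )
        beta = (
            network_response[:, net_index]
            + subject_trial[:, net_index]
            + offsets[net_index][None, :]
            + rng.normal(0.0, config.network_noise_sd, (len(latents), n_v))
        )
        betas[sid] = beta
        labels[sid] = label.astype(str)

    eta_frame = pd.DataFrame(eta, index=latents.index, columns=networks)
    return betas, labels, eta_frame


def render_bold(
    betas: np.ndarray,
    design: np.ndarray,
    n_trials: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Design-consistent BOLD time series: ``Y = X[:, :n_trials] @ B + noise``.

    Nuisance columns of the design carry true coefficient zero. With zero
    noise, refitting the GLM recovers ``betas`` to numerical precision.
    """
    if betas.shape[0] != n_trials:
        raise ValueError("betas rows must equal n_trials")
    y = design[:, :n_trials] @ betas
    if noise_sd:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return y


@dataclass
class SyntheticStudy:
    """A complete rendered study plus its generative ground truth."""

    config: GeneratorConfig
    metadata: pd.DataFrame
    trial_latents: pd.DataFrame
    sessions_exp1: list[RaterSession]
    sessions_exp2: list[RaterSession]
    betas: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    network_trial_noise: pd.DataFrame = field(repr=False)

    @property
    def truth_types(self) -> dict[str, str]:
        """rater_id -> contamination type for every contaminated session."""
        return {
            s.rater_id: s.truth_type
            for s in self.sessions_exp1 + self.sessions_exp2
            if s.truth_type is not None
        }

    def true_network_response(self) -> pd.DataFrame:
        """Noise-free group-level trial x network response, ``W f + eta``."""
        f = self.trial_latents[list(self.config.factor_names)].to_numpy()
        w = self.config.network_loading.to_numpy()
        resp = pd.DataFrame(
            f @ w.T,
            index=self.trial_latents.index,
            columns=list(self.config.network_loading.index),
        )
        return resp + self.network_trial_noise


def simulate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Render a full study deterministically from ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_latents, rng_sessions, rng_networks = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    metadata = trial_metadata(config)
    latents = sample_trial_latents(config, metadata, rng_latents)
    exp1, exp2 = render_rating_sessions(latents, config, metadata, rng_sessions)
    betas, labels, eta = render_network_responses(latents, config, rng_networks)
    return SyntheticStudy(
        config=config,
        metadata=metadata,
        trial_latents=latents,
        sessions_exp1=exp1,
        sessions_exp2=exp2,
        betas=betas,
        labels=labels,
        network_trial_noise=eta,
    )
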