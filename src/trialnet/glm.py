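"""Trial-wise GLM ("beta-series") estimation and network-level aggregation.

Each trial gets its own boxcar regressor convolved with a canonical
double-gamma hemodynamic response function; ordinary least squares per vertex
yields a trials x vertices beta matrix. Betas are then averaged over the
vertices of each individually defined network and across subjects, giving one
response estimate per network per unique trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import NETWORKS

VALID_NETWORKS = frozenset(NETWORKS) | {"unassigned"}


@dataclass
class RunDesign:
    """Timing of one task run: 10 s trials with 10 s ISI at TR = 1 s by default."""

    tr: float = 1.0
    n_volumes: int = 612  # 10 min 12 s
    onsets: tuple[float, ...] = tuple(float(20 * i) for i in range(30))
    trial_duration: float = 10.0
    add_drift: bool = True

    def __post_init__(self) -> None:
        run_len = self.n_volumes * self.tr
        if any(o + self.trial_duration > run_len for o in self.onsets):
            raise ValueError("trial onset+duration past end of run")
        if any(o < 0 for o in self.onsets):
            raise ValueError("negative onset")


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical HRF: gamma response peaking at 6 s minus a 16 s undershoot
    (ratio 1/6), sampled on the TR grid and peak-normalized."""
    t = np.arange(0, duration, tr)
    peak = stats.gamma.pdf(t, a=6, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def build_design(run: RunDesign, hrf: str = "double_gamma") -> np.ndarray:
    """Design matrix: one convolved boxcar column per trial, then an intercept
    and (optionally) a linear drift column.

    ``hrf='delta'`` skips convolution, leaving raw boxcars (each column then
    sums to duration/TR).
    """
    n_trials = len(run.onsets)
    columns = []
    kernel = None if hrf == "delta" else double_gamma_hrf(run.tr)
    if hrf not in ("delta", "double_gamma"):
        raise ValueError(f"unknown hrf: {hrf}")
    grid = np.arange(run.n_volumes) * run.tr
    for onset in run.onsets:
        box = ((grid >= onset) & (grid < onset + run.trial_duration)).astype(float)
        col = box if kernel is None else np.convolve(box, kernel)[: run.n_volumes]
        columns.append(col)
    columns.append(np.ones(run.n_volumes))
    if run.add_drift:
        drift = np.linspace(-1.0, 1.0, run.n_volumes)
        columns.append(drift)
    x = np.column_stack(columns)
    if n_trials and np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return x


@dataclass
class BetaMatrix:
    subject: str
    values: np.ndarray  # trials x vertices
    residual_variance: np.ndarray | None = None  # per vertex


def fit_trial_betas(
    bold: np.ndarray, design: np.ndarray, n_trials: int, subject: str = ""
) -> BetaMatrix:
    """OLS per vertex; the first ``n_trials`` design columns are the trial
    regressors, the rest nuisance."""
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(design, bold, rcond=None)
    resid = bold - design @ coef
    dof = max(design.shape[0] - design.shape[1], 1)
    return BetaMatrix(
        subject=subject,
        values=coef[:n_trials],
        residual_variance=(resid**2).sum(axis=0) / dof,
    )


@dataclass
class NetworkTrialResponse:
    """Trial x network mean betas; per subject or group-averaged."""

    values: pd.DataFrame  # index: trial_id, columns: network
    subjects: tuple[str, ...] = field(default_factory=tuple)


def network_mean_response(
    betas: np.ndarray,
    labels: np.ndarray,
    trial_ids: np.ndarray | None = None,
    subject: str = "",
) -> NetworkTrialResponse:
    """Unweighted mean beta over each network's member vertices, per trial."""
    if betas.shape[1] != len(labels):
        raise ValueError("betas and labels disagree on vertex count")
    networks = [n for n in NETWORKS if n in set(labels)]
    if not networks:
        raise ValueError("no labeled network has any vertices")
    data = {}
    for net in networks:
        mask = labels == net
        if not mask.any():
            raise ValueError(f"network {net} has zero vertices")
        data[net] = betas[:, mask].mean(axis=1)
    idx = trial_ids if trial_ids is not None else np.arange(1, betas.shape[0] + 1)
    values = pd.DataFrame(data, index=pd.Index(idx, name="trial_id"))
    return NetworkTrialResponse(values=values, subjects=(subject,) if subject else ())


def group_average(responses: list[NetworkTrialResponse]) -> NetworkTrialResponse:
    """Arithmetic mean over subjects, per trial per network."""
    if not responses:
        raise ValueError("no subject responses to average")
    frames = [r.values for r in responses]
    stacked = pd.concat(frames, keys=range(len(frames)))
    mean = stacked.groupby(level=1, sort=False).mean()
    counts = stacked.groupby(level=1, sort=False).size()
    if (counts < 1).any():
        raise ValueError("trial absent for all subjects")
    mean.index.name = "trial_id"
    subjects = tuple(s for r in responses for s in r.subjects)
    return NetworkTrialResponse(values=mean, subjects=subjects)
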