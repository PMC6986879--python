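"""Participation-ratio dimensionality of the PRP electrode space.

For M channels with covariance eigenvalues lambda_i, the effective
dimensionality is dim = (sum lambda_i)^2 / sum lambda_i^2: it equals M
when all eigenvalues are equal and m when exactly m equal eigenvalues
are nonzero.  The time course is computed per 0.1 s bin from the
covariance of the per-trial PRP vectors, per (odorant, stage) group, and
normalized to the mean pre-trial (baseline-window) dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prp import PrpTensor
from .session import AnalysisConfig

__all__ = [
    "DimResult",
    "DimTimecourse",
    "participation_ratio",
    "dim_timecourse",
    "pool_sessions",
]


@dataclass
class DimResult:
    lambdas: np.ndarray
    dim: float
    n_channels: int


@dataclass
class DimTimecourse:
    timebins_s: np.ndarray
    dim: np.ndarray  # per bin; NaN where undefined
    normalized_dim: np.ndarray
    baseline_dim: float
    n_channels: int
    group: tuple[str, str]  # (odorant, stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timebin_s": self.timebins_s,
                "odorant": self.group[0],
                "stage": self.group[1],
                "dim": self.dim,
                "normalized_dim": self.normalized_dim,
            }
        )


def participation_ratio(lambdas: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2, with negative numerical eigenvalues floored at 0."""
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam < -1e-9 * max(1.0, np.abs(lam).max())):
        warnings.warn("significantly negative eigenvalues floored at 0")
    lam = np.maximum(lam, 0.0)
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero eigenvalue spectrum: dimensionality undefined")
    return float(total**2 / np.sum(lam**2))


def _cov_dim(x: np.ndarray) -> float:
    """Participation ratio of the channel covariance of (trials, channels) data."""
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    lam = np.linalg.eigvalsh(cov)
    return participation_ratio(lam)


def dim_timecourse(
    tensor: PrpTensor,
    config: AnalysisConfig | None = None,
    per_group: bool = True,
) -> list[DimTimecourse]:
    """Participation-ratio time course, one per (odorant, stage) group.

    With ``per_group=False`` all trials are combined into a single
    group labelled ("all", "all").  Bins whose covariance is identically
    zero yield NaN.
    """
    config = config or AnalysisConfig()
    if tensor.n_trials < tensor.n_electrodes + 2:
        warnings.warn(
            f"only {tensor.n_trials} trials for {tensor.n_electrodes} channels; "
            "covariance estimate will be noisy"
        )
    if per_group:
        keys = [
            (o, s)
            for o in np.unique(tensor.odorants)
            for s in np.unique(tensor.stages)
            if np.any((tensor.odorants == o) & (tensor.stages == s))
        ]
    else:
        keys = [("all", "all")]

    b0, b1 = config.baseline_window_s
    baseline_bins = (tensor.timebins_s >= b0) & (tensor.timebins_s < b1)
    out = []
    for odorant, stage in keys:
        if per_group:
            mask = (tensor.odorants == odorant) & (tensor.stages == stage)
        else:
            mask = np.ones(tensor.n_trials, dtype=bool)
        vals = tensor.values_db[mask]  # (trials, electrodes, bins)
        if vals.shape[0] < 3:
            continue
        dims = np.full(tensor.timebins_s.size, np.nan)
        for j in range(tensor.timebins_s.size):
            try:
                dims[j] = _cov_dim(vals[:, :, j])
            except ValueError:
                pass
        baseline = float(np.nanmean(dims[baseline_bins]))
        out.append(
            DimTimecourse(
                timebins_s=tensor.timebins_s,
                dim=dims,
                normalized_dim=dims / baseline,
                baseline_dim=baseline,
                n_channels=tensor.n_electrodes,
                group=(str(odorant), str(stage)),
            )
        )
    return out


def pool_sessions(tensors: list[PrpTensor]) -> PrpTensor:
    """Concatenate electrodes across sessions into one pooled tensor.

    Channels become 16 x N for N sessions; per odorant, the trial count
    is truncated to the minimum across sessions (the first n trials of
    each session in order).
    """
    if len(tensors) == 0:
        raise ValueError("pool_sessions: no tensors")
    if len(tensors) == 1:
        return tensors[0]
    ref = tensors[0]
    odorants = np.unique(np.concatenate([t.odorants for t in tensors]))
    per_odorant_min = {}
    for o in odorants:
        counts = [int(np.sum(t.odorants == o)) for t in tensors]
        if min(counts) == 0:
            raise ValueError(f"pool_sessions: a session has no {o} trials")
        per_odorant_min[o] = min(counts)

    blocks, meta = [], None
    for o in odorants:
        n = per_odorant_min[o]
        sub = [t.select_trials(t.odorants == o) for t in tensors]
        sub = [s.select_trials(np.arange(s.n_trials) < n) for s in sub]
        values = np.concatenate([s.values_db for s in sub], axis=1)
        odor_mean = np.concatenate([s.odor_window_mean_db for s in sub], axis=1)
        blocks.append((values, odor_mean, sub[0]))
    values = np.concatenate([b[0] for b in blocks], axis=0)
    odor_mean = np.concatenate([b[1] for b in blocks], axis=0)
    first = blocks[0][2]
    return PrpTensor(
        values_db=values,
        reference=ref.reference,
        band=ref.band,
        timebins_s=ref.timebins_s,
        odor_window_mean_db=odor_mean,
        trial_index=np.arange(values.shape[0]),
        odorants=np.concatenate([np.repeat(o, per_odorant_min[o]) for o in odorants]),
        stages=np.concatenate(
            [b[2].stages[: per_odorant_min[o]] for o, b in zip(odorants, blocks)]
        ),
        outcomes=np.concatenate(
            [b[2].outcomes[: per_odorant_min[o]] for o, b in zip(odorants, blocks)]
        ),
        session_id="pooled",
    )
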