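"""Trial-wise decoding of odorant contextual identity from PRP.

A two-class linear discriminant with pooled within-class covariance is
trained on all trials but one and evaluated on the held-out trial,
repeated over trials (leave-one-out cross-validation), independently in
every 0.1 s bin with the per-electrode PRP as features.  A shuffle
control repeats the procedure with permuted training labels.  Decoding
accuracy over the odor window is summarized as a normalized area under
the curve: 0 at chance (50%) and 1 at perfect decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prp import PrpTensor
from .session import AnalysisConfig, SessionValidationError

__all__ = [
    "DecodingTimecourse",
    "lda_loocv",
    "decode_timecourse",
    "pc1_timecourse",
    "normalized_auc",
]


@dataclass
class DecodingTimecourse:
    timebins_s: np.ndarray
    accuracy: np.ndarray  # % correct per bin
    shuffled_mean: np.ndarray
    shuffled_lo: np.ndarray
    shuffled_hi: np.ndarray
    correct: np.ndarray  # (trials, bins) held-out correctness, 0/1
    odorants: np.ndarray
    outcomes: np.ndarray
    per_outcome_accuracy: dict[str, np.ndarray] = field(default_factory=dict)
    auc: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "timebin_s": self.timebins_s,
                "accuracy": self.accuracy,
                "shuffled_mean": self.shuffled_mean,
                "shuffled_lo": self.shuffled_lo,
                "shuffled_hi": self.shuffled_hi,
            }
        )
        for outcome, acc in self.per_outcome_accuracy.items():
            frame[f"accuracy_{outcome}"] = acc
        return frame


def _lda_fit_scores(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Linear discriminant scores (>0 -> class 1) for test_x.

    Pooled within-class covariance with a small ridge toward the
    diagonal (eps = 1e-6 * trace / M) keeps the solve well-posed when
    trials barely outnumber electrodes.
    """
    mu0 = train_x[train_y == 0].mean(axis=0)
    mu1 = train_x[train_y == 1].mean(axis=0)
    centered = train_x - np.where(train_y[:, None] == 1, mu1, mu0)
    m = train_x.shape[1]
    cov = centered.T @ centered / max(train_x.shape[0] - 2, 1)
    eps = 1e-6 * np.trace(cov) / m
    cov = cov + (eps if eps > 0 else 1e-12) * np.eye(m)
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -0.5 * (mu1 + mu0) @ w + np.log(
        np.sum(train_y == 1) / np.sum(train_y == 0)
    )
    return np.atleast_2d(test_x) @ w + b


def lda_loocv(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Leave-one-out LDA: per-trial held-out predictions and accuracy (%).

    Labels may be any two values (e.g. "S+"/"S-"); predictions are
    returned in the same label space.  Exact ties in the discriminant
    score are broken by a seeded coin flip.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise SessionValidationError(f"need exactly 2 classes, got {classes.size}")
    y = (labels == classes[1]).astype(int)
    if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
        raise SessionValidationError("each class needs at least 2 trials")
    n = features.shape[0]
    rng = np.random.default_rng(seed)
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        score = _lda_fit_scores(features[mask], y[mask], features[i])[0]
        if score == 0.0:
            pred[i] = int(rng.integers(2))
        else:
            pred[i] = int(score > 0)
        mask[i] = True
    accuracy = 100.0 * float(np.mean(pred == y))
    return classes[pred], accuracy


def normalized_auc(
    accuracy: np.ndarray,
    timebins_s: np.ndarray,
    odor_window_s: tuple[float, float] = (0.5, 2.5),
) -> float:
    """Mean above-chance accuracy over the odor window, scaled to [0, 1].

    50% maps to 0 and 100% to 1; accuracy below chance is clipped to
    chance so the area never rewards anti-learning.
    """
    acc = np.asarray(accuracy, dtype=float)
    t = np.asarray(timebins_s, dtype=float)
    window = (t >= odor_window_s[0]) & (t <= odor_window_s[1])
    return float(np.mean(np.maximum(acc[window] - 50.0, 0.0)) / 50.0)


def decode_timecourse(
    tensor: PrpTensor,
    config: AnalysisConfig | None = None,
    n_shuffles: int | None = None,
    seed: int = 0,
) -> DecodingTimecourse:
    """Per-bin LOOCV LDA with shuffle control and per-outcome accuracy.

    The caller is expected to pass a stage-filtered tensor (naive and
    proficient trial ranges are analyzed separately).  The shuffle
    control permutes training labels only; its 95% interval is the
    normal-approximation spread (mean +/- 1.96 sd) of the shuffle
    accuracy distribution.  Bins where decoding fails (degenerate class
    counts) are NaN.
    """
    config = config or AnalysisConfig()
    n_shuffles = config.n_shuffles if n_shuffles is None else n_shuffles
    rng = np.random.default_rng(seed)
    n_trials, _, n_bins = tensor.values_db.shape
    labels = tensor.odorants
    accuracy = np.full(n_bins, np.nan)
    shuffled = np.full((n_shuffles, n_bins), np.nan)
    correct = np.full((n_trials, n_bins), np.nan)

    y = (labels == "S+").astype(int)
    for j in range(n_bins):
        x = tensor.values_db[:, :, j]
        try:
            pred, acc = lda_loocv(x, labels, seed=int(rng.integers(2**31 - 1)))
        except SessionValidationError:
            continue
        accuracy[j] = acc
        correct[:, j] = (pred == labels).astype(float)
        for s in range(n_shuffles):
            perm = rng.permutation(n_trials)
            try:
                _, sacc = _loocv_shuffled(
                    x, y, perm, seed=int(rng.integers(2**31 - 1))
                )
            except SessionValidationError:
                continue
            shuffled[s, j] = sacc

    sh_mean = np.nanmean(shuffled, axis=0)
    sh_sd = np.nanstd(shuffled, axis=0, ddof=1)
    per_outcome = {}
    for outcome in ("Hit", "Miss", "CR", "FA"):
        mask = tensor.outcomes == outcome
        if np.any(mask):
            per_outcome[outcome] = 100.0 * np.nanmean(correct[mask], axis=0)

    tc = DecodingTimecourse(
        timebins_s=tensor.timebins_s,
        accuracy=accuracy,
        shuffled_mean=sh_mean,
        shuffled_lo=sh_mean - 1.96 * sh_sd,
        shuffled_hi=sh_mean + 1.96 * sh_sd,
        correct=correct,
        odorants=labels,
        outcomes=tensor.outcomes,
        per_outcome_accuracy=per_outcome,
    )
    tc.auc = normalized_auc(accuracy, tensor.timebins_s, config.odor_window_s)
    return tc


def _loocv_shuffled(
    x: np.ndarray, y: np.ndarray, perm: np.ndarray, seed: int
) -> tuple[np.ndarray, float]:
    """LOOCV under a permuted labeling: train and score against permuted labels.

    Re-running the identical estimator on a relabeled dataset is the
    permutation null: it shares the leave-one-out hold-out bias of the
    true-label estimate, which an accuracy scored against the unpermuted
    labels would not.
    """
    n = x.shape[0]
    y_perm = y[perm]
    rng = np.random.default_rng(seed)
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_y = y_perm[mask]
        if np.sum(train_y == 0) < 2 or np.sum(train_y == 1) < 2:
            raise SessionValidationError("shuffled class too small")
        score = _lda_fit_scores(x[mask], train_y, x[i])[0]
        pred[i] = int(rng.integers(2)) if score == 0.0 else int(score > 0)
        mask[i] = True
    return pred, 100.0 * float(np.mean(pred == y_perm))


def pc1_timecourse(
    tensor: PrpTensor,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """First-principal-component score time course per odorant.

    The principal axis is computed per time bin from the pooled
    (both-class) trials x electrodes matrix; the per-bin sign ambiguity
    of the axis is resolved so the S+ mean score in that bin is
    non-negative.  Zero-variance bins yield 0 scores.
    """
    config = config or AnalysisConfig()
    n_trials, _, n_bins = tensor.values_db.shape
    splus = tensor.odorants == "S+"
    scores = np.zeros((n_trials, n_bins))
    for j in range(n_bins):
        x = tensor.values_db[:, :, j]
        xc = x - x.mean(axis=0)
        if not np.any(xc):
            continue
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        s = xc @ vt[0]
        scores[:, j] = s if s[splus].mean() >= 0 else -s
    rows = []
    for odorant in np.unique(tensor.odorants):
        mask = tensor.odorants == odorant
        rows.append(
            pd.DataFrame(
                {
                    "timebin_s": tensor.timebins_s,
                    "odorant": odorant,
                    "pc1_mean": scores[mask].mean(axis=0),
                    "pc1_sd": scores[mask].std(axis=0, ddof=1),
                    "n_trials": int(mask.sum()),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
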