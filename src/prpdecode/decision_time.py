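"""Decision-time estimation from lick trains and decoder predictions.

For each 0.1 s bin the two odorants are compared with a two-sided
Wilcoxon rank-sum test — on binary lick presence (S+ vs S- trials), or
on per-trial decoder correctness (1 correct / 0 incorrect).  The
decision time is the earliest post-odor bin at which the p-value falls
below alpha and stays below it through the end of the odor period.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import lick_matrix
from .session import AnalysisConfig

__all__ = [
    "PValueSeries",
    "ranksum_pvalue",
    "decision_time",
    "lick_pvalue_series",
    "decoder_pvalue_series",
    "lick_and_decoder_decision_times",
]

EXACT_MAX_N = 9  # exact enumeration when the smaller sample is this size or less


@dataclass
class PValueSeries:
    timebins_s: np.ndarray
    p: np.ndarray
    source: str  # "licks", "lda_peak", "lda_trough", ...
    decision_time_s: float | None = None


def _exact_ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive two-sided rank-sum p over all C(n1+n2, n1) assignments.

    Midranks handle ties; p = 2 * min(P(T <= t), P(T >= t)), capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    t_obs = ranks[:n1].sum()
    total = comb(pooled.size, n1)
    le = ge = 0
    for subset in combinations(range(pooled.size), n1):
        t = ranks[list(subset)].sum()
        if t <= t_obs + 1e-9:
            le += 1
        if t >= t_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the smaller sample has <= 9 observations
    (valid under ties via midranks); otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ranksum_pvalue: empty sample")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values identical: no evidence
    if min(x.size, y.size) <= EXACT_MAX_N:
        return _exact_ranksum(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def decision_time(
    series: PValueSeries,
    alpha: float = 0.05,
    t_start: float = 0.0,
    t_end: float = 2.5,
) -> float | None:
    """Earliest sustained sub-alpha crossing between t_start and t_end.

    Returns the bin center of the first bin >= t_start whose p-value and
    all subsequent p-values through t_end are below alpha; None if the
    p-value never stays below alpha.
    """
    t = np.asarray(series.timebins_s, dtype=float)
    p = np.asarray(series.p, dtype=float)
    window = (t >= t_start) & (t <= t_end)
    tw, pw = t[window], p[window]
    below = pw < alpha
    # last index where p >= alpha; sustained crossing starts after it
    above_idx = np.flatnonzero(~below)
    start = 0 if above_idx.size == 0 else above_idx[-1] + 1
    if start >= below.size:
        return None
    return float(tw[start])


def lick_pvalue_series(
    trial_tables: list, config: AnalysisConfig | None = None
) -> PValueSeries:
    """Per-bin rank-sum p for S+ vs S- binary licks, pooled over sessions."""
    config = config or AnalysisConfig()
    grid = config.timebin_centers()
    mats, labels = [], []
    for table in trial_tables:
        usable = table.usable_mask()
        mats.append(lick_matrix(table, grid, config.timebin_s)[usable])
        labels.append(table.odorants[usable])
    licks = np.vstack(mats)
    odorants = np.concatenate(labels)
    p = np.array(
        [
            ranksum_pvalue(licks[odorants == "S+", j], licks[odorants == "S-", j])
            for j in range(grid.size)
        ]
    )
    series = PValueSeries(timebins_s=grid, p=p, source="licks")
    series.decision_time_s = decision_time(
        series, config.alpha, t_start=0.0, t_end=config.odor_window_s[1]
    )
    return series


def decoder_pvalue_series(
    correct: np.ndarray,
    odorants: np.ndarray,
    timebins_s: np.ndarray,
    source: str = "lda_peak",
    alpha: float = 0.05,
    t_end: float = 2.5,
) -> PValueSeries:
    """Per-bin rank-sum p for held-out decoder output, S+ vs S- trials.

    ``correct`` is (trials, bins) with 1 for a correct leave-one-out
    prediction and 0 otherwise.  The tested quantity is the predicted
    identity (1 = predicted S+): correctness on an S+ trial, one minus
    correctness on an S- trial.  Comparing raw correctness between the
    classes would never diverge — a decoder that is right on both
    classes scores ~1 on each — whereas the predicted identities
    separate exactly when decoding becomes informative.
    """
    correct = np.asarray(correct, dtype=float)
    odorants = np.asarray(odorants)
    splus = odorants == "S+"
    predicted_splus = np.where(splus[:, None], correct, 1.0 - correct)
    p = np.empty(timebins_s.size)
    for j in range(timebins_s.size):
        col = predicted_splus[:, j]
        ok = np.isfinite(col)
        p[j] = ranksum_pvalue(col[ok & splus], col[ok & ~splus])
    series = PValueSeries(timebins_s=np.asarray(timebins_s), p=p, source=source)
    series.decision_time_s = decision_time(series, alpha, t_start=0.0, t_end=t_end)
    return series


def lick_and_decoder_decision_times(
    trial_tables: list,
    decodings: dict[str, "object"],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Decision times per source: licks plus one row per decoder timecourse.

    ``decodings`` maps a source name (e.g. "lda_peak") to a
    :class:`prpdecode.decoding.DecodingTimecourse` computed on the same
    pooled trials.
    """
    config = config or AnalysisConfig()
    rows = []
    lick_series = lick_pvalue_series(trial_tables, config)
    rows.append({"source": "licks", "decision_time_s": lick_series.decision_time_s})
    for name, dec in decodings.items():
        series = decoder_pvalue_series(
            dec.correct,
            dec.odorants,
            dec.timebins_s,
            source=name,
            alpha=config.alpha,
            t_end=config.odor_window_s[1],
        )
        rows.append({"source": name, "decision_time_s": series.decision_time_s})
    return pd.DataFrame(rows)
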