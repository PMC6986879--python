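"""Resampling and multiple-comparison utilities shared by the analysis stages.

Confidence intervals are percentile bootstrap of the mean (1000
resamples by default); multiple comparisons use Benjamini-Hochberg
step-up FDR; pairwise post-hoc comparisons choose between a two-sample
t-test and the rank-sum test based on an Anderson-Darling normality
check of each sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BootstrapCI", "bootstrap_ci", "bh_fdr", "select_posthoc_test"]


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lo: float
    hi: float
    n_resamples: int


def bootstrap_ci(
    values: np.ndarray, n: int = 1000, level: float = 0.95, seed: int = 0
) -> BootstrapCI:
    """Percentile bootstrap CI of the mean, sampling with replacement."""
    values = np.sort(np.asarray(values, dtype=float))  # order-invariant resampling
    if values.size == 0:
        raise ValueError("bootstrap_ci: empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n, values.size))
    means = values[idx].mean(axis=1)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [tail, 1.0 - tail])
    return BootstrapCI(point=float(values.mean()), lo=float(lo), hi=float(hi), n_resamples=n)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up.

    Returns (rejected flags, pFDR) where pFDR is the largest p(k) with
    p(k) <= k*q/m among the rejected hypotheses (0 if none), matching
    the 'p < pFDR' reporting convention.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([], dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    rejected = np.zeros(m, dtype=bool)
    if not np.any(below):
        return rejected, 0.0
    k_max = int(np.max(np.flatnonzero(below)))
    rejected[order[: k_max + 1]] = True
    return rejected, float(ranked[k_max])


def _anderson_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True if the Anderson-Darling test does not reject normality at alpha."""
    x = np.asarray(x, dtype=float)
    try:
        res = stats.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue > alpha)
    except TypeError:  # older scipy: compare against tabulated critical values
        res = stats.anderson(x, dist="norm")
        sig = np.asarray(res.significance_level, dtype=float)
        i = int(np.argmin(np.abs(sig - alpha * 100.0)))
        return res.statistic < res.critical_values[i]


def select_posthoc_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """Pick a two-sample test by per-pair normality gating.

    Both samples consistent with normality (Anderson-Darling, 5%) ->
    two-sample t-test; otherwise rank-sum.  Returns (test name, p).
    """
    from .decision_time import ranksum_pvalue

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.array_equal(x, y) and np.ptp(x) == 0:
        # degenerate identical constant samples: no evidence either way
        return "t_test", 1.0
    if _anderson_normal(x, alpha) and _anderson_normal(y, alpha):
        return "t_test", float(stats.ttest_ind(x, y).pvalue)
    return "ranksum", ranksum_pvalue(x, y)
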