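"""Behavioral scoring for the go/no-go odor discrimination task.

A trial is scored from its lick times (trial-aligned, seconds from the
final-valve diversion).  The response area is four consecutive 0.5 s
blocks; licking in every block on a rewarded (S+) trial is a Hit, on an
unrewarded (S-) trial a False Alarm.  Performance is the percentage of
correct responses (Hit or Correct Rejection) in a trailing 20-trial
window, and sessions are segmented into naive (<= 65%), intermediate,
and proficient (>= 80%) trial ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SessionValidationError, Trial

__all__ = [
    "BehaviorTimecourse",
    "classify_outcome",
    "sliding_performance",
    "segment_stages",
    "lick_binarize",
    "lick_matrix",
]

NAIVE_MAX_PC = 65.0
PROFICIENT_MIN_PC = 80.0
RESPONSE_BLOCK_S = 0.5
N_RESPONSE_BLOCKS = 4


@dataclass
class BehaviorTimecourse:
    percent_correct: np.ndarray
    stage_mask: np.ndarray
    lick_matrix: np.ndarray  # (trials, timebins), binary


def classify_outcome(trial: Trial, response_onset_s: float = 0.5) -> str:
    """Score one trial: lick in all four 0.5 s blocks = go response."""
    if trial.odorant not in ("S+", "S-"):
        raise SessionValidationError(f"missing/unknown odorant {trial.odorant!r}")
    licks = np.asarray(trial.lick_times_s, dtype=float)
    go = True
    for b in range(N_RESPONSE_BLOCKS):
        lo = response_onset_s + b * RESPONSE_BLOCK_S
        if not np.any((licks >= lo) & (licks < lo + RESPONSE_BLOCK_S)):
            go = False
            break
    if trial.odorant == "S+":
        return "Hit" if go else "Miss"
    return "FA" if go else "CR"


def sliding_performance(
    outcomes: list[str], window: int = 20, step: int = 1
) -> np.ndarray:
    """Percent correct (Hit or CR) in a trailing window, one value per trial.

    Trials before the first full window take the first full-window value;
    with fewer trials than the window, the single available-set value is
    used throughout.
    """
    correct = np.array([o in ("Hit", "CR") for o in outcomes], dtype=float)
    n = correct.size
    if n == 0:
        return np.array([])
    pc = np.empty(n)
    if n < window:
        pc[:] = 100.0 * correct.mean()
        return pc
    last = 100.0 * correct[:window].mean()
    for i in range(window - 1, n):
        if (i - (window - 1)) % step == 0:
            last = 100.0 * correct[i - window + 1 : i + 1].mean()
        pc[i] = last
    pc[: window - 1] = pc[window - 1]
    return pc


def segment_stages(percent_correct: np.ndarray) -> np.ndarray:
    """Map sliding performance to naive / intermediate / proficient labels."""
    pc = np.asarray(percent_correct, dtype=float)
    stages = np.full(pc.shape, "intermediate", dtype=object)
    stages[pc <= NAIVE_MAX_PC] = "naive"
    stages[pc >= PROFICIENT_MIN_PC] = "proficient"
    return stages.astype(str)


def lick_binarize(lick_times: np.ndarray, grid: np.ndarray, timebin_s: float = 0.1) -> np.ndarray:
    """0/1 per time bin: 1 if at least one lick fell in the bin.

    ``grid`` holds bin centers; licks are scored presence/absence, never
    counted.
    """
    licks = np.asarray(lick_times, dtype=float)
    out = np.zeros(grid.size, dtype=int)
    if licks.size == 0:
        return out
    lo = grid[0] - timebin_s / 2
    idx = np.floor((licks - lo) / timebin_s).astype(np.intp)
    ok = (idx >= 0) & (idx < grid.size)
    out[np.unique(idx[ok])] = 1
    return out


def lick_matrix(trial_table, grid: np.ndarray, timebin_s: float = 0.1) -> np.ndarray:
    """Stack per-trial binarized licks into a (trials, bins) matrix."""
    return np.vstack(
        [
            lick_binarize(np.asarray(t.lick_times_s), grid, timebin_s)
            for t in trial_table.trials
        ]
    )
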