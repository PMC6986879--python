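"""Domain types and on-disk representation of a go/no-go LFP session.

A session is a continuous multi-electrode recording around which a trial
structure is defined: each trial has a start time, an odorant-valve
diversion time (the origin of trial-aligned time), an odorant label
(``S+`` rewarded / ``S-`` unrewarded), lick times, and a behavioral
outcome (Hit / Miss / CR / FA).

On disk a session is a directory::

    metadata.json   rate, electrode_count, duration_s, ids, label map
    lfp.f32         electrode-major float32 little-endian voltage (uV)
    trials.csv      one row per trial
    licks.f32       optional lick trace, float32

All times are seconds as 64-bit floats.  Trial-aligned time is measured
from the final-valve diversion (``odor_on_s``), not odorant arrival at
the nose; ``AnalysisConfig.odor_arrival_offset_s`` can shift it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandSpec",
    "AnalysisConfig",
    "Trial",
    "TrialTable",
    "LfpSession",
    "SessionFormatError",
    "SessionValidationError",
    "DEFAULT_BANDS",
    "load_session",
    "save_session",
]

ODORANTS = ("S+", "S-")
OUTCOMES = ("Hit", "Miss", "CR", "FA", "undefined")
STAGES = ("naive", "intermediate", "proficient")


class SessionFormatError(ValueError):
    """Raised when on-disk session files are inconsistent with metadata."""


class SessionValidationError(ValueError):
    """Raised when in-memory session fields violate their invariants."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, ``0 < low_hz < high_hz``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise SessionValidationError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )

    def validate_rate(self, rate: float) -> None:
        if self.high_hz >= rate / 2:
            raise SessionValidationError(
                f"band {self.name!r} upper edge {self.high_hz} Hz is at or above "
                f"Nyquist ({rate / 2} Hz)"
            )


#: Default analysis bands: theta carrier for phase, beta and high gamma
#: for amplitude.  Theta 6-14 Hz; an alternative 2-14 Hz definition is in
#: use for respiratory-locked rhythms and can be passed explicitly.
DEFAULT_BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 6.0, 14.0),
    "theta_wide": BandSpec("theta_wide", 2.0, 14.0),
    "beta": BandSpec("beta", 15.0, 30.0),
    "high_gamma": BandSpec("high_gamma", 65.0, 95.0),
}


@dataclass
class AnalysisConfig:
    """Parameters shared by all analysis stages.

    Defaults follow the conventions of the analysis: 51 phase bins, 0.1 s
    time bins, odor scoring window 0.5-2.5 s after valve diversion,
    baseline window [-1, 0) s, order-20 zero-phase Butterworth filtering,
    7-cycle Morlet wavelets, 1000 bootstrap resamples.
    """

    bands: dict[str, BandSpec] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    n_phase_bins: int = 51
    timebin_s: float = 0.1
    odor_window_s: tuple[float, float] = (0.5, 2.5)
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    trial_grid_s: tuple[float, float] = (-1.5, 4.0)
    pac_window_s: tuple[float, float] = (0.0, 2.5)
    filter_order: int = 20
    filter_pad_s: float = 0.5
    wavelet_cycles: float = 7.0
    n_bootstrap: int = 1000
    n_shuffles: int = 20
    alpha: float = 0.05
    odor_arrival_offset_s: float = 0.0
    phase_origin_deg: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phase_bins < 3:
            raise SessionValidationError("n_phase_bins must be >= 3")
        lo, hi = self.odor_window_s
        glo, ghi = self.trial_grid_s
        if not (glo <= lo < hi <= ghi):
            raise SessionValidationError(
                "odor_window_s must lie within trial_grid_s"
            )

    def timebin_centers(self) -> np.ndarray:
        """Centers of the trial-aligned 0.1 s grid."""
        lo, hi = self.trial_grid_s
        n = int(round((hi - lo) / self.timebin_s))
        return lo + (np.arange(n) + 0.5) * self.timebin_s


@dataclass
class Trial:
    trial_start_s: float
    odor_on_s: float
    odorant: str
    outcome: str = "undefined"
    lick_times_s: list[float] = field(default_factory=list)
    reinforced: bool = False

    def __post_init__(self) -> None:
        if self.odorant not in ODORANTS:
            raise SessionValidationError(f"unknown odorant label {self.odorant!r}")
        if self.outcome not in OUTCOMES:
            raise SessionValidationError(f"unknown outcome {self.outcome!r}")
        if self.odor_on_s < self.trial_start_s:
            raise SessionValidationError("odor_on_s must be >= trial_start_s")
        if self.outcome in ("Hit", "Miss") and self.odorant != "S+":
            raise SessionValidationError(f"{self.outcome} outcome requires S+")
        if self.outcome in ("CR", "FA") and self.odorant != "S-":
            raise SessionValidationError(f"{self.outcome} outcome requires S-")


@dataclass
class TrialTable:
    """Ordered trials with derived behavioral annotations.

    ``percent_correct`` is the 20-trial sliding performance and
    ``stage_mask`` the naive/intermediate/proficient segmentation; both
    are recomputed from the outcomes rather than stored on disk.
    """

    trials: list[Trial]
    percent_correct: np.ndarray | None = None
    stage_mask: np.ndarray | None = None
    outcomes_derived: bool = False

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def odorants(self) -> np.ndarray:
        return np.array([t.odorant for t in self.trials])

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials])

    @property
    def odor_on_times(self) -> np.ndarray:
        return np.array([t.odor_on_s for t in self.trials])

    def annotate(self) -> "TrialTable":
        """Fill percent_correct and stage_mask from the outcomes."""
        from .behavior import segment_stages, sliding_performance

        self.percent_correct = sliding_performance(list(self.outcomes))
        self.stage_mask = segment_stages(self.percent_correct)
        return self

    def select(self, mask: np.ndarray) -> "TrialTable":
        idx = np.flatnonzero(np.asarray(mask))
        sub = TrialTable(
            [self.trials[i] for i in idx],
            outcomes_derived=self.outcomes_derived,
        )
        if self.percent_correct is not None:
            sub.percent_correct = self.percent_correct[idx]
            sub.stage_mask = self.stage_mask[idx]
        return sub

    def usable_mask(self) -> np.ndarray:
        """Trials with a defined outcome (aborted trials are excluded)."""
        return self.outcomes != "undefined"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "trial": i,
                    "trial_start_s": t.trial_start_s,
                    "odor_on_s": t.odor_on_s,
                    "odorant": t.odorant,
                    "outcome": t.outcome,
                    "reinforced": t.reinforced,
                    "lick_times_s": ";".join(repr(x) for x in t.lick_times_s),
                }
            )
        frame = pd.DataFrame(rows)
        if self.percent_correct is not None:
            frame["percent_correct"] = self.percent_correct
            frame["stage"] = self.stage_mask
        return frame


@dataclass
class LfpSession:
    """Continuous multi-electrode voltage with its event timeline."""

    samples: np.ndarray  # (electrodes, time), float32 uV
    rate: float = 20000.0
    events: list[tuple[str, float]] = field(default_factory=list)
    lick_trace: np.ndarray | None = None
    session_id: str = "session"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise SessionValidationError("samples must be 2-D (electrodes x time)")
        if self.rate <= 0:
            raise SessionValidationError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError("samples contain non-finite values")
        dur = self.duration_s
        for label, t in self.events:
            if not (0.0 <= t <= dur):
                raise SessionValidationError(
                    f"event {label!r} at {t} s outside [0, {dur}] s"
                )

    @property
    def electrode_count(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate

    def time_to_index(self, t: float) -> int:
        return int(round(t * self.rate))


def _trials_to_csv(table: TrialTable) -> str:
    lines = ["trial_start_s,odor_on_s,odorant,outcome,reinforced,lick_times_s"]
    for t in table.trials:
        licks = ";".join(repr(x) for x in t.lick_times_s)
        lines.append(
            f"{t.trial_start_s!r},{t.odor_on_s!r},{t.odorant},"
            f"{t.outcome},{int(t.reinforced)},{licks}"
        )
    return "\n".join(lines) + "\n"


def save_session(session: LfpSession, trial_table: TrialTable, path: str | Path) -> Path:
    """Write a session directory; byte output is deterministic."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create session directory {path}: {exc}") from exc

    meta = {
        "rate": session.rate,
        "electrode_count": session.electrode_count,
        "n_samples": session.samples.shape[1],
        "duration_s": session.duration_s,
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "odorant_labels": {"S+": "rewarded", "S-": "unrewarded"},
        "events": [[label, t] for label, t in session.events],
        "has_lick_trace": session.lick_trace is not None,
    }
    (path / "metadata.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )
    session.samples.astype("<f4").tofile(path / "lfp.f32")
    (path / "trials.csv").write_text(_trials_to_csv(trial_table))
    if session.lick_trace is not None:
        np.asarray(session.lick_trace, dtype="<f4").tofile(path / "licks.f32")
    return path


def _parse_licks(cell: str) -> list[float]:
    if not isinstance(cell, str) or cell == "":
        return []
    return [float(x) for x in cell.split(";")]


def load_session(path: str | Path) -> tuple[LfpSession, TrialTable]:
    """Load a session directory written by :func:`save_session`.

    If ``trials.csv`` omits the outcome column, outcomes are recomputed
    from lick times with :func:`prpdecode.behavior.classify_outcome` and
    the table is flagged ``outcomes_derived``.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    lfp_path = path / "lfp.f32"
    trials_path = path / "trials.csv"
    for p in (meta_path, lfp_path, trials_path):
        if not p.exists():
            raise FileNotFoundError(f"missing session file: {p}")

    meta = json.loads(meta_path.read_text())
    m = int(meta["electrode_count"])
    n = int(meta["n_samples"])
    raw = np.fromfile(lfp_path, dtype="<f4")
    if raw.size != m * n:
        raise SessionFormatError(
            f"{lfp_path}: expected {m} electrodes x {n} samples = {m * n} "
            f"float32 values, found {raw.size}"
        )
    samples = raw.reshape(m, n)

    lick_trace = None
    if meta.get("has_lick_trace") and (path / "licks.f32").exists():
        lick_trace = np.fromfile(path / "licks.f32", dtype="<f4")

    session = LfpSession(
        samples=samples,
        rate=float(meta["rate"]),
        events=[(label, float(t)) for label, t in meta.get("events", [])],
        lick_trace=lick_trace,
        session_id=str(meta.get("session_id", path.name)),
        subject_id=str(meta.get("subject_id", "subject")),
    )

    frame = pd.read_csv(
        trials_path,
        keep_default_na=False,
        dtype={"lick_times_s": str},
        float_precision="round_trip",
    )
    derived = "outcome" not in frame.columns
    trials: list[Trial] = []
    for _, row in frame.iterrows():
        odorant = str(row["odorant"])
        if odorant not in ODORANTS:
            raise SessionValidationError(
                f"{trials_path}: unknown odorant label {odorant!r}"
            )
        trial = Trial(
            trial_start_s=float(row["trial_start_s"]),
            odor_on_s=float(row["odor_on_s"]),
            odorant=odorant,
            outcome="undefined" if derived else str(row["outcome"]),
            lick_times_s=_parse_licks(row.get("lick_times_s", "")),
            reinforced=bool(int(row["reinforced"])) if "reinforced" in frame.columns else odorant == "S+",
        )
        trials.append(trial)

    if derived:
        from .behavior import classify_outcome

        trials = [replace(t, outcome=classify_outcome(t)) for t in trials]

    table = TrialTable(trials, outcomes_derived=derived).annotate()
    return session, table
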