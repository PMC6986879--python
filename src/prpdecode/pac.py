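"""Phase-amplitude coupling (PAC) of low-frequency phase and high-frequency amplitude.

The chain follows the Hilbert-transform estimator: zero-phase Butterworth
band filtering of the raw LFP, instantaneous phase of the slow band and
amplitude envelope of the fast band from the analytic signal, a 51-bin
normalized distribution of mean envelope over phase, and the modulation
index (MI) — the Kullback-Leibler distance of that distribution from
uniform, normalized by ln(N) so MI is 0 for uniform coupling and 1 for a
delta distribution.

Phase convention: 0 degrees at the waveform maximum of the slow band
(the angle of the analytic signal of a cosine), increasing through the
cycle, reported in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .session import AnalysisConfig, BandSpec, LfpSession, SessionValidationError, TrialTable

__all__ = [
    "PacDistribution",
    "PacTrialSeries",
    "bandpass_filter",
    "butter_sos",
    "phase_and_envelope",
    "pac_distribution",
    "modulation_index",
    "peak_angle_variance",
    "session_pac",
]


@dataclass
class PacDistribution:
    """Normalized amplitude-by-phase distribution with its summary numbers."""

    bin_centers_deg: np.ndarray
    p: np.ndarray
    mi: float
    entropy_nats: float
    peak_phase_deg: float
    trough_phase_deg: float

    @property
    def n_bins(self) -> int:
        return self.p.size


@dataclass
class PacTrialSeries:
    """Per-trial, per-electrode PAC summaries in long format.

    Columns: trial, electrode, odorant, stage, outcome, mi,
    peak_phase_deg, trough_phase_deg.
    """

    table: pd.DataFrame
    group_distributions: dict[tuple[str, str], PacDistribution] = field(default_factory=dict)
    reference_peak_deg: np.ndarray | None = None  # per electrode, from S+ trials
    reference_trough_deg: np.ndarray | None = None


def butter_sos(band: BandSpec, rate: float, order: int = 20) -> np.ndarray:
    """Design the band-pass Butterworth in second-order sections.

    A direct transfer-function realization is numerically unstable at
    order 20; the cascaded-biquad form is exact in design and stable.
    """
    band.validate_rate(rate)
    return butter(order, (band.low_hz, band.high_hz), btype="band", fs=rate, output="sos")


def bandpass_filter(
    signal: np.ndarray, band: BandSpec, rate: float, order: int = 20
) -> np.ndarray:
    """Zero-phase (forward-backward) band-pass filter, same length as input."""
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise SessionValidationError("bandpass_filter: non-finite samples")
    sos = butter_sos(band, rate, order)
    return sosfiltfilt(sos, signal, axis=-1)


def phase_and_envelope(
    filtered_low: np.ndarray,
    filtered_high: np.ndarray,
    origin_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (deg, [0, 360)) of the slow band and envelope of the fast band.

    ``origin_deg`` shifts the phase origin; the default places 0 degrees
    at the waveform maximum (cosine convention).
    """
    filtered_low = np.asarray(filtered_low, dtype=float)
    filtered_high = np.asarray(filtered_high, dtype=float)
    if filtered_low.shape != filtered_high.shape:
        raise SessionValidationError("phase/envelope inputs must have equal shape")
    if np.max(np.abs(filtered_low)) == 0:
        raise SessionValidationError("all-zero slow-band signal: phase undefined")
    phase_deg = (np.degrees(np.angle(hilbert(filtered_low))) - origin_deg) % 360.0
    envelope = np.abs(hilbert(filtered_high))
    return phase_deg, envelope


def _bin_index(phase_deg: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(np.asarray(phase_deg) / 360.0 * n_bins).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def modulation_index(p: np.ndarray) -> float:
    """MI = (ln N - H) / ln N for a normalized distribution p."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise SessionValidationError("distribution has negative mass")
    if abs(p.sum() - 1.0) > 1e-6:
        raise SessionValidationError(f"distribution not normalized (sum={p.sum()})")
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return (np.log(p.size) - entropy) / np.log(p.size)


def pac_distribution(
    phase_deg: np.ndarray, envelope: np.ndarray, n_bins: int = 51
) -> PacDistribution:
    """Mean-envelope-by-phase distribution, normalized to sum to one."""
    phase_deg = np.asarray(phase_deg, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if phase_deg.shape != envelope.shape:
        raise SessionValidationError("phase and envelope must have equal length")
    if n_bins < 3:
        raise SessionValidationError("n_bins must be >= 3")
    idx = _bin_index(phase_deg, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise SessionValidationError(
            "empty phase bin: input too short to populate all bins"
        )
    mean_env = np.bincount(idx, weights=envelope, minlength=n_bins) / counts
    p = mean_env / mean_env.sum()
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return PacDistribution(
        bin_centers_deg=centers,
        p=p,
        mi=(np.log(n_bins) - entropy) / np.log(n_bins),
        entropy_nats=entropy,
        peak_phase_deg=float(centers[np.argmax(p)]),
        trough_phase_deg=float(centers[np.argmin(p)]),
    )


def peak_angle_variance(peak_phases_deg: np.ndarray, kind: str = "circular") -> float:
    """Across-trial variance of peak angles.

    ``kind='circular'`` (default) returns the circular variance
    ``1 - R`` where R is the mean resultant length, in [0, 1].
    ``kind='unwrapped'`` returns the ordinary variance of the angles in
    squared degrees after centering on the circular mean.
    """
    angles = np.radians(np.asarray(peak_phases_deg, dtype=float))
    if angles.size == 0:
        raise SessionValidationError("peak_angle_variance: empty input")
    z = np.exp(1j * angles)
    mean_z = z.mean()
    if kind == "circular":
        return float(1.0 - np.abs(mean_z))
    if kind == "unwrapped":
        centered = np.angle(z * np.conj(mean_z / max(np.abs(mean_z), 1e-300)))
        return float(np.degrees(centered).var())
    raise ValueError(f"unknown kind {kind!r}")


def analytic_bands(
    session: LfpSession,
    low_band: BandSpec,
    high_band: BandSpec,
    config: AnalysisConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-electrode continuous phase (deg) and envelope for the whole recording.

    Filtering the continuous trace once and slicing trial windows
    afterwards avoids per-window filter transients; windows are
    additionally padded by ``config.filter_pad_s`` when sliced.
    """
    low = bandpass_filter(session.samples, low_band, session.rate, config.filter_order)
    high = bandpass_filter(session.samples, high_band, session.rate, config.filter_order)
    phase = (
        np.degrees(np.angle(hilbert(low, axis=-1))) - config.phase_origin_deg
    ) % 360.0
    envelope = np.abs(hilbert(high, axis=-1))
    return phase, envelope


def session_pac(
    session: LfpSession,
    trial_table: TrialTable,
    low_band: BandSpec,
    high_band: BandSpec,
    config: AnalysisConfig | None = None,
) -> PacTrialSeries:
    """Per-trial/electrode PAC over the odor-aligned analysis window.

    Group distributions are reported for every (odorant, stage) with
    trials present.  The session reference peak/trough phases — the
    phases later used for phase-referenced power — are computed per
    electrode from the pooled S+ trials only.
    """
    config = config or AnalysisConfig()
    phase, envelope = analytic_bands(session, low_band, high_band, config)
    w0, w1 = config.pac_window_s

    usable = trial_table.usable_mask()
    if not np.any((trial_table.odorants == "S+") & usable):
        raise SessionValidationError(
            "session_pac: no S+ trials; reference phases undefined"
        )

    rows = []
    pooled: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    splus_pooled: list[list[tuple[np.ndarray, np.ndarray]]] = [
        [] for _ in range(session.electrode_count)
    ]
    stages = (
        trial_table.stage_mask
        if trial_table.stage_mask is not None
        else np.full(len(trial_table), "proficient")
    )
    for k, trial in enumerate(trial_table.trials):
        if not usable[k]:
            continue
        i0 = session.time_to_index(trial.odor_on_s + w0)
        i1 = session.time_to_index(trial.odor_on_s + w1)
        if i0 < 0 or i1 > session.samples.shape[1]:
            continue
        for e in range(session.electrode_count):
            dist = pac_distribution(
                phase[e, i0:i1], envelope[e, i0:i1], config.n_phase_bins
            )
            rows.append(
                {
                    "trial": k,
                    "electrode": e,
                    "odorant": trial.odorant,
                    "stage": stages[k],
                    "outcome": trial.outcome,
                    "mi": dist.mi,
                    "peak_phase_deg": dist.peak_phase_deg,
                    "trough_phase_deg": dist.trough_phase_deg,
                }
            )
            pooled.setdefault((trial.odorant, str(stages[k])), []).append(
                (phase[e, i0:i1], envelope[e, i0:i1])
            )
            if trial.odorant == "S+":
                splus_pooled[e].append((phase[e, i0:i1], envelope[e, i0:i1]))

    table = pd.DataFrame(rows)
    series = PacTrialSeries(table=table)

    for key, chunks in pooled.items():
        ph = np.concatenate([c[0] for c in chunks])
        env = np.concatenate([c[1] for c in chunks])
        series.group_distributions[key] = pac_distribution(ph, env, config.n_phase_bins)

    peaks = np.empty(session.electrode_count)
    troughs = np.empty(session.electrode_count)
    for e in range(session.electrode_count):
        ph = np.concatenate([c[0] for c in splus_pooled[e]])
        env = np.concatenate([c[1] for c in splus_pooled[e]])
        dist = pac_distribution(ph, env, config.n_phase_bins)
        peaks[e] = dist.peak_phase_deg
        troughs[e] = dist.trough_phase_deg
    series.reference_peak_deg = peaks
    series.reference_trough_deg = troughs
    return series
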