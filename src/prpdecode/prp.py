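"""Theta phase-referenced power (PRP).

Band power is estimated with a continuous complex Morlet wavelet
transform (power averaged over a 1 Hz grid of center frequencies
spanning the band, in dB re 1 uV^2) and sampled once per theta cycle at
a fixed reference phase — the peak or trough of the session's
phase-amplitude distribution measured from rewarded (S+) trials.  The
sampled values are averaged within 0.1 s bins on the trial-aligned grid;
bins without a theta crossing are filled by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .inference import bootstrap_ci
from .pac import analytic_bands, session_pac
from .session import AnalysisConfig, BandSpec, LfpSession, TrialTable

__all__ = [
    "PrpTensor",
    "morlet_band_power",
    "reference_crossing_times",
    "trial_prp",
    "session_prp",
    "prp_summary",
]


@dataclass
class PrpTensor:
    """Phase-referenced power on the trial-aligned grid.

    values_db has shape (trials, electrodes, timebins); trial k of the
    tensor corresponds to row ``trial_index[k]`` of the trial table it
    was built from.
    """

    values_db: np.ndarray
    reference: str  # "peak" or "trough"
    band: BandSpec
    timebins_s: np.ndarray
    odor_window_mean_db: np.ndarray  # (trials, electrodes)
    trial_index: np.ndarray
    odorants: np.ndarray
    stages: np.ndarray
    outcomes: np.ndarray
    session_id: str = "session"

    @property
    def n_trials(self) -> int:
        return self.values_db.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values_db.shape[1]

    def select_trials(self, mask: np.ndarray) -> "PrpTensor":
        idx = np.flatnonzero(np.asarray(mask))
        return PrpTensor(
            values_db=self.values_db[idx],
            reference=self.reference,
            band=self.band,
            timebins_s=self.timebins_s,
            odor_window_mean_db=self.odor_window_mean_db[idx],
            trial_index=self.trial_index[idx],
            odorants=self.odorants[idx],
            stages=self.stages[idx],
            outcomes=self.outcomes[idx],
            session_id=self.session_id,
        )

    def to_frame(self) -> pd.DataFrame:
        t_idx, e_idx, b_idx = np.meshgrid(
            np.arange(self.n_trials),
            np.arange(self.n_electrodes),
            np.arange(self.timebins_s.size),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "trial": self.trial_index[t_idx.ravel()],
                "electrode": e_idx.ravel(),
                "timebin_s": self.timebins_s[b_idx.ravel()],
                "reference": self.reference,
                "db": self.values_db.ravel(),
            }
        )


def _morlet_kernel(freq: float, rate: float, cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L1-normalized gaussian envelope.

    With this normalization the response to a unit-amplitude sinusoid at
    the center frequency has magnitude 1/2, so power = 2|W|^2 recovers
    the sinusoid's mean power a^2/2.
    """
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    gauss /= gauss.sum()
    return gauss * np.exp(2j * np.pi * freq * t)


def morlet_band_power(
    signal: np.ndarray,
    rate: float,
    band: BandSpec,
    wavelet_cycles: float = 7.0,
    freq_step_hz: float = 1.0,
) -> np.ndarray:
    """Band power time series in dB re 1 uV^2.

    The squared wavelet magnitude at each 1 Hz-spaced center frequency
    estimates the local PSD smoothed by the wavelet's spectral window
    (power-response sd s = f/cycles); summing over the grid with the
    resolution correction step/(sqrt(pi)*s) integrates the PSD over the
    band, so a sinusoid at a mid-band frequency reads its true mean
    power a^2/2.  Works on 1-D signals or (channels, time) arrays.
    """
    signal = np.asarray(signal, dtype=float)
    band.validate_rate(rate)
    freqs = np.arange(np.ceil(band.low_hz), np.floor(band.high_hz) + 0.5, freq_step_hz)
    n = signal.shape[-1]
    power = np.zeros_like(signal, dtype=float)
    for f in freqs:
        kernel = _morlet_kernel(f, rate, wavelet_cycles)
        if kernel.size > n:
            raise ValueError(
                f"wavelet support ({kernel.size} samples at {f} Hz) exceeds "
                f"signal length ({n})"
            )
        shape = (1,) * (signal.ndim - 1) + (kernel.size,)
        w = fftconvolve(signal, kernel.reshape(shape), mode="same", axes=-1)
        spectral_sd = f / wavelet_cycles
        power += 2.0 * np.abs(w) ** 2 * freq_step_hz / (np.sqrt(np.pi) * spectral_sd)
    return 10.0 * np.log10(np.maximum(power, 1e-300))


def reference_crossing_times(
    theta_phase_deg: np.ndarray,
    reference_deg: float,
    rate: float = 1.0,
    min_separation_s: float = 0.0,
) -> np.ndarray:
    """Times (s) where the phase passes ``reference_deg`` in the increasing direction.

    One crossing per completed cycle.  With ``rate=1`` the return values
    are sample indices.  ``min_separation_s`` debounces jitter around the
    reference phase.
    """
    d = (np.asarray(theta_phase_deg, dtype=float) - reference_deg) % 360.0
    wraps = np.flatnonzero(np.diff(d) < -180.0) + 1
    if min_separation_s > 0 and wraps.size > 1:
        keep = [wraps[0]]
        min_gap = min_separation_s * rate
        for w in wraps[1:]:
            if w - keep[-1] >= min_gap:
                keep.append(w)
        wraps = np.array(keep)
    return wraps / rate


def _bin_crossing_samples(
    times_rel_s: np.ndarray,
    values_db: np.ndarray,
    grid: np.ndarray,
    timebin_s: float,
) -> np.ndarray:
    """Average dB samples into grid bins; interpolate/fill empty bins."""
    lo = grid[0] - timebin_s / 2
    idx = np.floor((times_rel_s - lo) / timebin_s).astype(np.intp)
    ok = (idx >= 0) & (idx < grid.size)
    counts = np.bincount(idx[ok], minlength=grid.size)
    sums = np.bincount(idx[ok], weights=values_db[ok], minlength=grid.size)
    out = np.full(grid.size, np.nan)
    filled = counts > 0
    out[filled] = sums[filled] / counts[filled]
    if not np.any(filled):
        return out
    if not np.all(filled):
        out = np.interp(grid, grid[filled], out[filled])
    return out


def trial_prp(
    session: LfpSession,
    trial,
    electrode: int,
    band: BandSpec,
    reference_phase_deg: float,
    config: AnalysisConfig | None = None,
    theta_band: BandSpec | None = None,
) -> np.ndarray:
    """Phase-referenced power for one trial/electrode on the trial-aligned grid.

    Convenience path for single trials; bulk analysis should use
    :func:`session_prp`, which filters the continuous recording once.
    """
    from .session import DEFAULT_BANDS

    config = config or AnalysisConfig()
    theta_band = theta_band or DEFAULT_BANDS["theta"]
    grid = config.timebin_centers()
    pad = config.filter_pad_s
    t0 = trial.odor_on_s + config.trial_grid_s[0] - pad
    t1 = trial.odor_on_s + config.trial_grid_s[1] + pad
    i0, i1 = session.time_to_index(max(t0, 0.0)), session.time_to_index(t1)
    if i1 > session.samples.shape[1]:
        warnings.warn("trial window truncated at end of recording")
        i1 = session.samples.shape[1]
    seg = LfpSession(
        samples=session.samples[electrode : electrode + 1, i0:i1],
        rate=session.rate,
        session_id=session.session_id,
        subject_id=session.subject_id,
    )
    phase, _ = analytic_bands(seg, theta_band, band, config)
    power_db = morlet_band_power(seg.samples[0], session.rate, band, config.wavelet_cycles)
    cross = reference_crossing_times(
        phase[0],
        reference_phase_deg,
        session.rate,
        min_separation_s=0.3 / theta_band.high_hz,
    )
    rel = cross + i0 / session.rate - trial.odor_on_s
    samples = np.interp(cross, np.arange(power_db.size) / session.rate, power_db)
    return _bin_crossing_samples(rel, samples, grid, config.timebin_s)


def session_prp(
    session: LfpSession,
    trial_table: TrialTable,
    band: BandSpec,
    config: AnalysisConfig | None = None,
    theta_band: BandSpec | None = None,
    references: tuple[str, ...] = ("peak", "trough"),
    pac_series=None,
) -> dict[str, PrpTensor]:
    """PRP tensors for the whole session, keyed by reference phase kind.

    Reference phases are per electrode, from the S+ phase-amplitude
    distributions (``pac_series``; computed here if not given), and held
    fixed for both odorants and stages within the session.
    """
    from .session import DEFAULT_BANDS

    config = config or AnalysisConfig()
    theta_band = theta_band or DEFAULT_BANDS["theta"]
    if pac_series is None:
        pac_series = session_pac(session, trial_table, theta_band, band, config)

    grid = config.timebin_centers()
    phase, _ = analytic_bands(session, theta_band, band, config)
    power_db = morlet_band_power(
        session.samples, session.rate, band, config.wavelet_cycles
    )

    usable = np.flatnonzero(trial_table.usable_mask())
    stages = (
        trial_table.stage_mask
        if trial_table.stage_mask is not None
        else np.full(len(trial_table), "proficient")
    )
    ref_phases = {
        "peak": pac_series.reference_peak_deg,
        "trough": pac_series.reference_trough_deg,
    }

    w0, w1 = config.odor_window_s
    in_odor = (grid >= w0) & (grid <= w1)
    out: dict[str, PrpTensor] = {}
    for ref in references:
        values = np.empty((usable.size, session.electrode_count, grid.size))
        for e in range(session.electrode_count):
            cross = reference_crossing_times(
                phase[e],
                float(ref_phases[ref][e]),
                session.rate,
                min_separation_s=0.3 / theta_band.high_hz,
            )
            cross_db = np.interp(
                cross, np.arange(power_db.shape[1]) / session.rate, power_db[e]
            )
            for row, k in enumerate(usable):
                rel = cross - trial_table.trials[k].odor_on_s
                values[row, e] = _bin_crossing_samples(
                    rel, cross_db, grid, config.timebin_s
                )
        out[ref] = PrpTensor(
            values_db=values,
            reference=ref,
            band=band,
            timebins_s=grid,
            odor_window_mean_db=values[:, :, in_odor].mean(axis=2),
            trial_index=usable,
            odorants=trial_table.odorants[usable],
            stages=np.asarray(stages)[usable],
            outcomes=trial_table.outcomes[usable],
            session_id=session.session_id,
        )
    return out


def prp_summary(
    tensors: dict[str, PrpTensor] | PrpTensor,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-electrode group means of odor-window PRP with bootstrap 95% CI.

    Groups are (reference, odorant, stage); groups with fewer than two
    trials are omitted with a warning.
    """
    if isinstance(tensors, PrpTensor):
        tensors = {tensors.reference: tensors}
    rng = np.random.default_rng(seed)
    rows = []
    for ref, tensor in tensors.items():
        for odorant in np.unique(tensor.odorants):
            for stage in np.unique(tensor.stages):
                mask = (tensor.odorants == odorant) & (tensor.stages == stage)
                if mask.sum() < 2:
                    if mask.sum() == 1:
                        warnings.warn(
                            f"group ({ref}, {odorant}, {stage}) has a single "
                            "trial; omitted"
                        )
                    continue
                vals = tensor.odor_window_mean_db[mask]  # (trials, electrodes)
                for e in range(tensor.n_electrodes):
                    ci = bootstrap_ci(
                        vals[:, e],
                        n=n_bootstrap,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    rows.append(
                        {
                            "reference": ref,
                            "odorant": odorant,
                            "stage": stage,
                            "electrode": e,
                            "mean_db": ci.point,
                            "ci_lo": ci.lo,
                            "ci_hi": ci.hi,
                            "n_trials": int(mask.sum()),
                        }
                    )
    return pd.DataFrame(rows)
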