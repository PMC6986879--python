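"""Synthetic LFP generators.

Two generators live here:

* :func:`simulate_pac_signal` — the two-oscillation validation signal:
  an 8 Hz cosine plus a 40 Hz cosine, either uncoupled (constant
  amplitude) or with 40 Hz bursts created by multiplying the fast cosine
  by a periodic gaussian train (FWHM half a slow cycle) centered at a
  fixed phase of the slow cosine.

* :func:`simulate_session` — a full go/no-go session: a jittered theta
  carrier shared across electrodes; beta and high-gamma bursts coupled
  to a configurable theta phase with von Mises across-trial phase
  jitter; odor-epoch amplitude gains that differ by odorant valence and
  learning stage; a low-rank latent gain structure mixed across
  electrodes (controlling the participation-ratio dimensionality of the
  phase-referenced power); and lick trains whose S+/S- divergence time,
  hit rate, and false-alarm rate are configurable, so behavioral
  outcomes emerge from the licks themselves.

Both generators are deterministic for a fixed configuration and seed,
and return a ground-truth record for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import BandSpec, LfpSession, Trial, TrialTable

__all__ = [
    "SimulationConfig",
    "OdorantProfile",
    "StageProfile",
    "BandGenSpec",
    "SessionConfig",
    "simulate_pac_signal",
    "simulate_session",
    "analytic_envelope_mi",
    "proficient_config",
    "naive_config",
    "null_config",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimulationConfig:
    """Two-oscillation validation signal parameters."""

    f_low_hz: float = 8.0
    f_high_hz: float = 40.0
    coupling: str = "none"  # "none" or "burst"
    burst_center_deg: float = 180.0
    burst_fwhm_s: float = (1.0 / 8.0) / 2.0
    low_amp: float = 1.0
    burst_amp: float = 1.0
    baseline_high_amp: float = 0.05
    duration_s: float = 20.0
    rate: float = 20000.0

    def __post_init__(self) -> None:
        if self.burst_fwhm_s <= 0:
            raise ValueError("burst_fwhm_s must be positive")
        if self.rate <= 2 * self.f_high_hz:
            raise ValueError("rate must exceed twice the fast frequency")
        if self.f_high_hz <= self.f_low_hz:
            raise ValueError("fast frequency must exceed slow frequency")
        if self.coupling not in ("none", "burst"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


def simulate_pac_signal(config: SimulationConfig = SimulationConfig()) -> np.ndarray:
    """Deterministic two-cosine signal, optionally with phase-locked bursts."""
    t = np.arange(int(round(config.duration_s * config.rate))) / config.rate
    low = config.low_amp * np.cos(2 * np.pi * config.f_low_hz * t)
    high = np.cos(2 * np.pi * config.f_high_hz * t)
    if config.coupling == "none":
        return low + config.burst_amp * high
    phase = (2 * np.pi * config.f_low_hz * t) % (2 * np.pi)
    center = np.radians(config.burst_center_deg)
    dt = (((phase - center + np.pi) % (2 * np.pi)) - np.pi) / (
        2 * np.pi * config.f_low_hz
    )
    sigma = config.burst_fwhm_s * FWHM_TO_SIGMA
    bursts = np.exp(-(dt**2) / (2 * sigma**2))
    return low + (config.baseline_high_amp + config.burst_amp * bursts) * high


@dataclass(frozen=True)
class OdorantProfile:
    """Neural + behavioral parameters for one odorant within one stage."""

    peak_phase_deg: float = 120.0
    phase_jitter_kappa: float = 50.0  # von Mises concentration; 0 = uniform
    odor_gain_db: float = 0.0  # amplitude gain during the odor epoch
    shared_gain_sd: float = 0.05  # trial-common gain fluctuation during odor
    p_go: float = 0.5  # probability of a sustained (go) lick response


@dataclass(frozen=True)
class StageProfile:
    splus: OdorantProfile
    sminus: OdorantProfile


@dataclass(frozen=True)
class BandGenSpec:
    """High-frequency burst band: carrier frequency and amplitudes (uV)."""

    name: str
    carrier_hz: float
    burst_amp_uv: float = 30.0
    baseline_frac: float = 0.15  # tonic carrier amplitude / burst amplitude
    fwhm_deg: float = 180.0  # burst width in theta phase


DEFAULT_GEN_BANDS = (
    BandGenSpec("beta", 22.0),
    BandGenSpec("high_gamma", 80.0),
)


@dataclass(frozen=True)
class SessionConfig:
    """Full go/no-go session generator parameters.

    Sessions are synthesized at 1 kHz by default: every analyzed band
    lies below 100 Hz, and the lower rate keeps full-session analysis
    cheap.  Real recordings are sampled at 20 kHz; set ``rate``
    accordingly if needed.
    """

    n_electrodes: int = 16
    n_trials: int = 100
    rate: float = 1000.0
    trial_period_s: float = 7.0
    pre_odor_s: float = 2.0  # odor valve opens this long after trial start
    odor_duration_s: float = 2.5
    odor_response_onset_s: float = 0.0  # neural gain latency after valve diversion
    theta_freq_hz: float = 8.0
    theta_freq_sd: float = 0.3
    theta_amp_uv: float = 100.0
    bands: tuple[BandGenSpec, ...] = DEFAULT_GEN_BANDS
    stage_schedule: tuple[tuple[str, int], ...] = (("proficient", 100),)
    profiles: dict[str, StageProfile] = field(default_factory=dict)
    n_latent_sources: int = 3
    latent_sd: float = 0.1
    latent_tau_s: float = 0.1  # latent gains redrawn every tau (burst power fluctuates)
    sensor_noise_uv: float = 1.0
    lick_rate_hz: float = 7.0
    lick_start_s: float = -1.0  # licking begins this long before odor on
    go_lick_end_s: float = 3.0
    nogo_stop_mean_s: float = 0.25  # S+/S- lick divergence latency
    nogo_stop_jitter_s: float = 0.05
    include_lfp: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_latent_sources > self.n_electrodes:
            raise ValueError("n_latent_sources must be <= n_electrodes")
        if sum(n for _, n in self.stage_schedule) != self.n_trials:
            raise ValueError("stage_schedule must cover exactly n_trials trials")
        for band in self.bands:
            if band.carrier_hz >= self.rate / 2:
                raise ValueError(f"band {band.name} carrier above Nyquist")
            if band.burst_amp_uv <= 0:
                raise ValueError(
                    f"band {band.name}: zero burst amplitude cannot express "
                    "a nonzero coupling target"
                )


PROFICIENT_STAGE = StageProfile(
    splus=OdorantProfile(
        peak_phase_deg=120.0,
        phase_jitter_kappa=50.0,
        odor_gain_db=6.0,
        shared_gain_sd=0.35,
        p_go=0.95,
    ),
    sminus=OdorantProfile(
        peak_phase_deg=120.0,
        phase_jitter_kappa=8.0,
        odor_gain_db=-6.0,
        shared_gain_sd=0.35,
        p_go=0.10,
    ),
)

NAIVE_STAGE = StageProfile(
    splus=OdorantProfile(
        peak_phase_deg=120.0,
        phase_jitter_kappa=3.0,
        odor_gain_db=0.0,
        shared_gain_sd=0.05,
        p_go=0.95,
    ),
    sminus=OdorantProfile(
        peak_phase_deg=120.0,
        phase_jitter_kappa=3.0,
        odor_gain_db=0.0,
        shared_gain_sd=0.05,
        p_go=0.85,
    ),
)


def proficient_config(n_trials: int = 100, seed: int = 0, **kwargs) -> SessionConfig:
    """A session where the animal discriminates: gains and licks diverge."""
    return SessionConfig(
        n_trials=n_trials,
        stage_schedule=(("proficient", n_trials),),
        profiles={"proficient": PROFICIENT_STAGE},
        rng_seed=seed,
        **kwargs,
    )


def naive_config(n_trials: int = 100, seed: int = 0, **kwargs) -> SessionConfig:
    """A session before learning: no S+/S- neural contrast, heavy FA licking."""
    return SessionConfig(
        n_trials=n_trials,
        stage_schedule=(("naive", n_trials),),
        profiles={"naive": NAIVE_STAGE},
        rng_seed=seed,
        **kwargs,
    )


def null_config(n_trials: int = 100, seed: int = 0, **kwargs) -> SessionConfig:
    """All S+/S- parameters identical: nothing distinguishes the odorants."""
    same = OdorantProfile(
        peak_phase_deg=120.0,
        phase_jitter_kappa=8.0,
        odor_gain_db=0.0,
        shared_gain_sd=0.05,
        p_go=0.5,
    )
    return SessionConfig(
        n_trials=n_trials,
        stage_schedule=(("proficient", n_trials),),
        profiles={"proficient": StageProfile(splus=same, sminus=same)},
        rng_seed=seed,
        **kwargs,
    )


def analytic_envelope_mi(
    baseline_frac: float, fwhm_deg: float, n_bins: int = 51
) -> float:
    """Modulation index implied by the generator's envelope profile.

    The within-trial fast-band envelope follows
    ``baseline + wrapped_gaussian(phase)``; integrating it over the
    phase bins gives the expected amplitude-by-phase distribution and
    hence the MI a noiseless measurement would recover.
    """
    sigma = fwhm_deg * FWHM_TO_SIGMA
    phi = np.linspace(0, 360, 20 * n_bins, endpoint=False)
    env = np.full_like(phi, baseline_frac)
    for wrap in (-360.0, 0.0, 360.0):
        env += np.exp(-((phi - 180.0 + wrap) ** 2) / (2 * sigma**2))
    bins = np.floor(phi / 360.0 * n_bins).astype(int)
    p = np.bincount(bins, weights=env, minlength=n_bins)
    p /= p.sum()
    entropy = -np.sum(p * np.log(p))
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


def _profile_for(config: SessionConfig, stage: str, odorant: str) -> OdorantProfile:
    profile = config.profiles.get(stage)
    if profile is None:
        profile = PROFICIENT_STAGE if stage == "proficient" else NAIVE_STAGE
    return profile.splus if odorant == "S+" else profile.sminus


def _lick_train(
    rng: np.random.Generator, config: SessionConfig, go: bool
) -> np.ndarray:
    """Trial-aligned lick times for one trial."""
    if go:
        end = config.go_lick_end_s
    else:
        end = config.nogo_stop_mean_s + rng.normal(0.0, config.nogo_stop_jitter_s)
        end = max(end, 0.05)
    period = 1.0 / config.lick_rate_hz
    times = []
    t = config.lick_start_s + rng.uniform(0, period)
    while t < end:
        times.append(t)
        t += period * (1.0 + 0.15 * rng.standard_normal())
    return np.array(times)


def _draw_odorants(rng: np.random.Generator, n_trials: int) -> np.ndarray:
    """Blocks of 20 trials with 10 S+ / 10 S- presented at random."""
    labels = []
    remaining = n_trials
    while remaining > 0:
        block = min(20, remaining)
        half = block // 2
        arr = np.array(["S+"] * half + ["S-"] * (block - half))
        rng.shuffle(arr)
        labels.extend(arr)
        remaining -= block
    return np.array(labels)


def simulate_session(
    config: SessionConfig = SessionConfig(),
) -> tuple[LfpSession, TrialTable, dict]:
    """Generate one synthetic go/no-go session.

    Returns (session, trial_table, truth): ``truth`` records the
    configured ground truth (per stage/odorant analytic MI per band,
    burst peak phase, odor gains, latent source count, lick divergence
    latency and go probabilities) for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.rng_seed)
    from .behavior import classify_outcome

    n = config.n_trials
    odorants = _draw_odorants(rng, n)
    stage_names = np.concatenate(
        [np.repeat(name, count) for name, count in config.stage_schedule]
    )
    trial_starts = (
        np.arange(n) * config.trial_period_s + rng.uniform(0.0, 0.25, size=n)
    )
    odor_on = trial_starts + config.pre_odor_s

    trials: list[Trial] = []
    for k in range(n):
        prof = _profile_for(config, stage_names[k], odorants[k])
        go = rng.random() < prof.p_go
        licks = _lick_train(rng, config, go)
        trial = Trial(
            trial_start_s=float(trial_starts[k]),
            odor_on_s=float(odor_on[k]),
            odorant=str(odorants[k]),
            lick_times_s=[float(x) for x in licks],
            reinforced=odorants[k] == "S+",
        )
        trial.outcome = classify_outcome(trial)
        trials.append(trial)

    duration_s = n * config.trial_period_s + 2.0
    n_samples = int(round(duration_s * config.rate))

    lick_trace = np.zeros(n_samples, dtype=np.float32)
    pulse = max(1, int(round(0.01 * config.rate)))
    for k, trial in enumerate(trials):
        for lt in trial.lick_times_s:
            i = int(round((trial.odor_on_s + lt) * config.rate))
            if 0 <= i < n_samples:
                lick_trace[i : i + pulse] = 1.0

    table = TrialTable(trials).annotate()
    truth: dict = {
        "n_latent_sources": config.n_latent_sources,
        "lick_divergence_s": config.nogo_stop_mean_s,
        "groups": {},
    }
    for stage in dict(config.stage_schedule):
        for odorant in ("S+", "S-"):
            prof = _profile_for(config, stage, odorant)
            truth["groups"][f"{stage}/{odorant}"] = {
                "peak_phase_deg": prof.peak_phase_deg,
                "phase_jitter_kappa": prof.phase_jitter_kappa,
                "odor_gain_db": prof.odor_gain_db,
                "p_go": prof.p_go,
                "mi_per_band": {
                    b.name: analytic_envelope_mi(b.baseline_frac, b.fwhm_deg)
                    for b in config.bands
                },
            }

    if not config.include_lfp:
        session = LfpSession(
            samples=np.zeros((config.n_electrodes, 1), dtype=np.float32),
            rate=config.rate,
            lick_trace=lick_trace,
            session_id=f"synthetic-{config.rng_seed}",
        )
        return session, table, truth

    # --- continuous per-sample trial attribution -------------------------
    t_grid = np.arange(n_samples) / config.rate
    trial_of_sample = np.clip(
        np.searchsorted(trial_starts, t_grid, side="right") - 1, 0, n - 1
    )

    # theta: per-trial frequency jitter, continuous phase
    freqs = config.theta_freq_hz + config.theta_freq_sd * rng.standard_normal(n)
    f_per_sample = freqs[trial_of_sample]
    phase = 2 * np.pi * np.cumsum(f_per_sample) / config.rate
    phase_deg = np.degrees(phase) % 360.0

    # odor-epoch mask per sample
    t_samples = t_grid
    odor_on_per_sample = odor_on[trial_of_sample]
    rel = t_samples - odor_on_per_sample
    in_odor = (rel >= config.odor_response_onset_s) & (rel < config.odor_duration_s)

    # latent gain structure: orthonormal mixing, equal source power.
    # Latents are redrawn every latent_tau_s so burst power fluctuates
    # within a trial (as cycle-to-cycle oscillatory power does); per
    # time bin and across trials the electrode covariance stays rank-m
    # with equal eigenvalues.
    m = config.n_latent_sources
    e_count = config.n_electrodes
    mixing, _ = np.linalg.qr(rng.standard_normal((e_count, m)))
    mixing *= np.sqrt(e_count / m)
    chunk_of_sample = (t_grid / config.latent_tau_s).astype(int)
    n_chunks = int(chunk_of_sample[-1]) + 1
    latents = config.latent_sd * rng.standard_normal((n_chunks, m))
    chunk_gain = np.clip(1.0 + latents @ mixing.T, 0.05, None)  # (chunks, E)

    # per-trial neural parameters: burst phase (von Mises jitter), odor
    # gain; the trial-common gain fluctuation (dimensionality collapse
    # during odor) is redrawn per chunk with the trial's sd.
    burst_center = np.empty(n)
    gain_lin = np.empty(n)
    shared_sd = np.empty(n)
    for k in range(n):
        prof = _profile_for(config, stage_names[k], odorants[k])
        kappa = prof.phase_jitter_kappa
        jitter = (
            rng.uniform(-np.pi, np.pi) if kappa == 0 else rng.vonmises(0.0, kappa)
        )
        burst_center[k] = prof.peak_phase_deg + np.degrees(jitter)
        gain_lin[k] = 10.0 ** (prof.odor_gain_db / 20.0)
        shared_sd[k] = prof.shared_gain_sd

    trial_of_chunk = trial_of_sample[
        np.minimum(
            (np.arange(n_chunks) * config.latent_tau_s * config.rate).astype(int),
            n_samples - 1,
        )
    ]
    shared_chunk = np.clip(
        1.0 + shared_sd[trial_of_chunk] * rng.standard_normal(n_chunks), 0.05, None
    )

    center_per_sample = burst_center[trial_of_sample]
    odorfac_per_sample = np.where(
        in_odor, gain_lin[trial_of_sample] * shared_chunk[chunk_of_sample], 1.0
    )

    theta_scale = 1.0 + 0.05 * rng.standard_normal(e_count)
    samples = np.empty((e_count, n_samples), dtype=np.float64)
    theta_wave = np.cos(phase)
    for e in range(e_count):
        samples[e] = config.theta_amp_uv * theta_scale[e] * theta_wave

    dphi = ((phase_deg - center_per_sample + 180.0) % 360.0) - 180.0
    for band in config.bands:
        sigma_deg = band.fwhm_deg * FWHM_TO_SIGMA
        envelope = band.baseline_frac + np.exp(-(dphi**2) / (2 * sigma_deg**2))
        carrier_phase = 2 * np.pi * band.carrier_hz * t_samples
        for e in range(e_count):
            amp = (
                band.burst_amp_uv
                * chunk_gain[chunk_of_sample, e]
                * odorfac_per_sample
            )
            samples[e] += (
                amp * envelope * np.cos(carrier_phase + rng.uniform(0, 2 * np.pi))
            )
    samples += config.sensor_noise_uv * rng.standard_normal(samples.shape)

    session = LfpSession(
        samples=samples.astype(np.float32),
        rate=config.rate,
        events=[("odor_on", float(t)) for t in odor_on],
        lick_trace=lick_trace,
        session_id=f"synthetic-{config.rng_seed}",
    )
    return session, table, truth
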