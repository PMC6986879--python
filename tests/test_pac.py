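"""Band filtering, Hilbert phase/envelope, phase-amplitude distributions, MI."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import sosfreqz

from prpdecode import (
    BandSpec,
    modulation_index,
    pac_distribution,
    peak_angle_variance,
    phase_and_envelope,
    bandpass_filter,
    session_pac,
)
from prpdecode.pac import butter_sos
from prpdecode.session import SessionValidationError

THETA = BandSpec("theta", 6.0, 14.0)
RATE = 2000.0


def _interior(x, frac=0.2):
    n = len(x)
    return x[int(n * frac) : int(n * (1 - frac))]


class TestBandpassFilter:
    def test_dc_fully_rejected(self):
        out = bandpass_filter(np.ones(20000), THETA, RATE)
        assert np.max(np.abs(_interior(out))) < 1e-6

    @pytest.mark.parametrize("freq,min_gain", [(10.0, None), (100.0, None)])
    def test_gain_matches_analytic_response(self, freq, min_gain):
        """Empirical pass-through agrees with the designed filter's |H|^2."""
        t = np.arange(int(30 * RATE)) / RATE
        x = np.cos(2 * np.pi * freq * t)
        y = _interior(bandpass_filter(x, THETA, RATE))
        empirical = np.sqrt(2) * np.std(y)
        sos = butter_sos(THETA, RATE)
        _, h = sosfreqz(sos, worN=[freq], fs=RATE)
        analytic = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
        if analytic > 1e-12:
            assert empirical == pytest.approx(analytic, rel=0.01)
        else:
            # deep stop band: spectral leakage floors the measurement
            assert empirical < 1e-4

    def test_stopband_attenuation_exceeds_60db(self):
        t = np.arange(int(30 * RATE)) / RATE
        y = _interior(bandpass_filter(np.cos(2 * np.pi * 100.0 * t), THETA, RATE))
        atten_db = -20 * np.log10(max(np.sqrt(2) * np.std(y), 1e-300))
        assert atten_db > 60

    def test_nyquist_violation_raises(self):
        with pytest.raises(SessionValidationError, match="Nyquist"):
            bandpass_filter(np.zeros(100), BandSpec("bad", 10, 1500), RATE)

    def test_nonfinite_samples_raise(self):
        x = np.zeros(1000)
        x[10] = np.nan
        with pytest.raises(SessionValidationError, match="finite"):
            bandpass_filter(x, THETA, RATE)


class TestPhaseEnvelope:
    def test_cosine_convention_zero_at_maximum(self):
        t = np.arange(int(4 * RATE)) / RATE
        low = np.cos(2 * np.pi * 8.0 * t)
        phase, _ = phase_and_envelope(low, low)
        # at an interior waveform maximum (t = 1.0 s) the phase is 0 deg
        i = int(1.0 * RATE)
        assert min(phase[i], 360 - phase[i]) < 1.0
        # phase advances 360 deg per cycle: 125 ms later it is 0 again
        j = i + int(0.125 * RATE)
        assert min(phase[j], 360 - phase[j]) < 1.0

    def test_constant_amplitude_envelope_flat(self):
        t = np.arange(int(4 * RATE)) / RATE
        high = 3.0 * np.cos(2 * np.pi * 40.0 * t)
        _, env = phase_and_envelope(np.cos(2 * np.pi * 8 * t), high)
        inner = _interior(env)
        assert np.all(np.abs(inner - 3.0) < 0.03)

    def test_burst_envelope_peaks_at_window_center(self):
        t = np.arange(int(4 * RATE)) / RATE
        center = 2.0
        window = np.exp(-((t - center) ** 2) / (2 * 0.05**2))
        high = window * np.cos(2 * np.pi * 40.0 * t)
        _, env = phase_and_envelope(np.cos(2 * np.pi * 8 * t), high)
        assert abs(t[np.argmax(env)] - center) < 0.002

    def test_all_zero_slow_band_raises(self):
        with pytest.raises(SessionValidationError, match="phase"):
            phase_and_envelope(np.zeros(100), np.ones(100))


class TestPacDistribution:
    def test_constant_envelope_is_uniform(self):
        phase = np.linspace(0, 360, 51 * 1000, endpoint=False)
        dist = pac_distribution(phase, np.ones_like(phase))
        assert dist.mi == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(dist.p, 1.0 / 51.0)

    def test_empty_bin_raises(self):
        phase = np.linspace(0, 180, 1000)  # half the cycle never visited
        with pytest.raises(SessionValidationError, match="bin"):
            pac_distribution(phase, np.ones(1000))

    def test_brute_force_histogram_oracle(self):
        """Vectorized distribution equals a per-sample python loop to 1e-12."""
        rng = np.random.default_rng(7)
        phase = rng.uniform(0, 360, 6000)
        env = rng.gamma(2.0, 1.0, 6000)
        dist = pac_distribution(phase, env, n_bins=51)
        sums = np.zeros(51)
        counts = np.zeros(51)
        for ph, e in zip(phase, env):
            j = min(int(ph / 360 * 51), 50)
            sums[j] += e
            counts[j] += 1
        p = (sums / counts) / np.sum(sums / counts)
        assert np.max(np.abs(p - dist.p)) < 1e-12
        h = -sum(q * np.log(q) for q in p if q > 0)
        assert dist.mi == pytest.approx((np.log(51) - h) / np.log(51), abs=1e-12)

    def test_circular_shift_moves_peak_not_mi(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(0, 360, 60000)
        env = 1.0 + np.cos(np.radians(phase - 120.0))
        base = pac_distribution(phase, env)
        for k in (5, 17, 30):  # whole-bin shifts keep the binning exact
            shift = k * 360.0 / 51.0
            shifted = pac_distribution((phase + shift) % 360.0, env)
            assert shifted.mi == pytest.approx(base.mi, abs=1e-9)
            expected = (base.peak_phase_deg + shift) % 360.0
            assert shifted.peak_phase_deg == pytest.approx(expected, abs=1e-9)


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert modulation_index(np.full(51, 1 / 51)) == pytest.approx(0.0, abs=1e-12)

    def test_delta_is_one(self):
        p = np.zeros(51)
        p[10] = 1.0
        assert modulation_index(p) == pytest.approx(1.0, abs=1e-12)

    def test_two_equal_bins_closed_form(self):
        p = np.zeros(51)
        p[[3, 40]] = 0.5
        assert modulation_index(p) == pytest.approx(1 - np.log(2) / np.log(51), abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(SessionValidationError, match="normalized"):
            modulation_index(np.full(51, 0.5))

    def test_envelope_scale_invariance(self):
        rng = np.random.default_rng(11)
        phase = rng.uniform(0, 360, 20000)
        env = rng.gamma(3.0, 1.0, 20000)
        base = pac_distribution(phase, env).mi
        for c in (1e-3, 2.7, 1e4):
            assert pac_distribution(phase, c * env).mi == pytest.approx(base, abs=1e-12)

    def test_monotone_in_von_mises_concentration(self):
        rng = np.random.default_rng(5)
        phase = rng.uniform(0, 360, 50000)
        mis = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            env = np.exp(kappa * np.cos(np.radians(phase - 180.0)))
            mis.append(pac_distribution(phase, env).mi)
        assert np.all(np.diff(mis) >= 0)


class TestPeakAngleVariance:
    def test_identical_angles_zero(self):
        assert peak_angle_variance([42.0] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_grid_approaches_one(self):
        angles = np.arange(1000) * 360.0 / 1000.0
        assert peak_angle_variance(angles) > 0.99

    def test_right_angle_pair(self):
        assert peak_angle_variance([0.0, 90.0]) == pytest.approx(
            1 - np.sqrt(2) / 2, abs=1e-12
        )

    def test_empty_raises(self):
        with pytest.raises(SessionValidationError):
            peak_angle_variance([])

    def test_unwrapped_variant(self):
        # symmetric +-30 deg around the circular mean: variance 900 deg^2
        assert peak_angle_variance([60.0, 120.0], kind="unwrapped") == pytest.approx(
            900.0, rel=1e-9
        )


class TestSessionPac:
    def test_reference_peak_recovers_generator_phase(self, proficient):
        err = np.abs(
            (proficient["pac"].reference_peak_deg - 120.0 + 180.0) % 360.0 - 180.0
        )
        assert np.all(err <= 15.0)

    def test_group_distribution_peak_near_generator_phase(self, proficient):
        dist = proficient["pac"].group_distributions[("S+", "proficient")]
        err = abs((dist.peak_phase_deg - 120.0 + 180.0) % 360.0 - 180.0)
        assert err <= 15.0

    def test_per_trial_mi_within_30pct_of_analytic(self, proficient):
        truth = proficient["truth"]["groups"]["proficient/S+"]["mi_per_band"][
            "high_gamma"
        ]
        measured = proficient["pac"].table.query("odorant == 'S+'").mi.mean()
        assert abs(measured - truth) / truth < 0.30

    def test_no_splus_trials_raises(self, config, proficient):
        table = proficient["table"].select(proficient["table"].odorants == "S-")
        with pytest.raises(SessionValidationError, match="S\\+"):
            session_pac(
                proficient["session"],
                table,
                config.bands["theta"],
                config.bands["high_gamma"],
                config,
            )

    def test_uncoupled_session_mi_near_zero(self, config):
        """A flat-envelope generator yields per-trial MI below 0.002."""
        from prpdecode.synthetic import (
            BandGenSpec,
            OdorantProfile,
            SessionConfig,
            StageProfile,
            simulate_session,
        )

        flat = (BandGenSpec("high_gamma", 80.0, burst_amp_uv=6.0,
                            baseline_frac=4.0, fwhm_deg=3600.0),)
        same = OdorantProfile(odor_gain_db=0.0, shared_gain_sd=0.0, p_go=0.5)
        cfg = SessionConfig(
            n_trials=20, n_electrodes=4, rate=500.0, bands=flat,
            stage_schedule=(("proficient", 20),),
            profiles={"proficient": StageProfile(same, same)},
            rng_seed=3,
        )
        sess, table, _ = simulate_session(cfg)
        pac = session_pac(
            sess, table, config.bands["theta"], config.bands["high_gamma"], config
        )
        assert pac.table.mi.mean() < 0.002

    def test_identical_stages_statistically_equal(self, config):
        """Two stages with identical parameters differ only by sampling noise."""
        from prpdecode.synthetic import (
            OdorantProfile,
            SessionConfig,
            StageProfile,
            simulate_session,
        )

        same = OdorantProfile(phase_jitter_kappa=8.0, odor_gain_db=0.0,
                              shared_gain_sd=0.05, p_go=0.5)
        profile = StageProfile(same, same)
        mi_a, mi_b = [], []
        for seed in range(8):
            cfg = SessionConfig(
                n_trials=24, n_electrodes=4, rate=500.0,
                stage_schedule=(("naive", 12), ("proficient", 12)),
                profiles={"naive": profile, "proficient": profile},
                rng_seed=seed,
            )
            sess, table, _ = simulate_session(cfg)
            pac = session_pac(
                sess, table, config.bands["theta"], config.bands["high_gamma"], config
            )
            frame = pac.table
            first = frame.trial < 12
            mi_a.extend(frame.mi[first])
            mi_b.extend(frame.mi[~first])
        assert stats.ks_2samp(mi_a, mi_b).pvalue > 0.01
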