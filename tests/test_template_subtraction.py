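"""AAS/OBS template correction, downsampling, and the filter bank."""

import numpy as np
import pytest

from emriclean.core_io import EEGRecording, Marker
from emriclean.synthetic_data import SimConfig, simulate_session
from emriclean.template_subtraction import (
    FilterPlan,
    TemplateConfig,
    aas_correct,
    apply_filters,
    bcg_correct,
    downsample,
    gradient_correct,
    obs_residual_removal,
    slice_frequency,
    slice_notches,
)


def _rec(data, rate=250.0, markers=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return EEGRecording(
        data=data,
        rate=rate,
        labels=[f"Ch{i}" for i in range(data.shape[0])],
        markers=markers or [],
    )


class TestAAS:
    def test_identical_artifact_annihilated(self):
        artifact = np.sin(np.linspace(0, 6 * np.pi, 80)) * 100.0
        events = np.arange(10) * 100 + 20
        data = np.zeros((2, 1100))
        for ev in events:
            data[:, ev : ev + 80] += artifact
        rec = _rec(data)
        out = aas_correct(
            rec, events, (0, 80), TemplateConfig(window=10, robust_exclude=None)
        )
        scale = np.abs(artifact).max()
        for ev in events:
            np.testing.assert_allclose(
                out.data[:, ev : ev + 80] / scale, 0.0, atol=1e-9
            )

    def test_samples_outside_epochs_untouched(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 1000))
        events = np.array([100, 300, 500])
        rec = _rec(data)
        out = aas_correct(rec, events, (0, 50), TemplateConfig(window=3))
        mask = np.ones(1000, dtype=bool)
        for ev in events:
            mask[ev : ev + 50] = False
        np.testing.assert_array_equal(out.data[:, mask], data[:, mask])

    def test_white_noise_residual_matches_monte_carlo_oracle(self):
        """Centered-mean subtraction of sigma^2=1 noise leaves a predictable
        residual variance; compare against a direct oracle on 10,000
        epochs."""
        rng = np.random.default_rng(42)
        n_ep, length, window = 10_000, 30, 16

        # oracle: same centered sliding-mean subtraction applied to an
        # independent stack of simulated epochs
        stack = rng.standard_normal((n_ep, length))
        resid = np.empty_like(stack)
        half = window // 2
        for j in range(n_ep):
            lo = max(0, j - half)
            hi = min(n_ep, lo + window)
            lo = max(0, hi - window)
            resid[j] = stack[j] - stack[lo:hi].mean(axis=0)
        oracle_var = resid.var()

        events = np.arange(n_ep) * length
        data = rng.standard_normal((1, n_ep * length))
        rec = _rec(data)
        out = aas_correct(
            rec, events, (0, length), TemplateConfig(window=window, robust_exclude=None)
        )
        assert out.data.var() == pytest.approx(oracle_var, rel=0.10)

    def test_single_event_raises(self):
        rec = _rec(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="2 events"):
            aas_correct(rec, [10], (0, 10), TemplateConfig(window=2))

    def test_subsample_alignment_improves_jittered_artifact_removal(self):
        """With sub-sample timing jitter (unsynchronized clocks), aligned
        templates leave a smaller residual than unaligned ones."""
        rng = np.random.default_rng(9)
        t_hi = np.arange(0, 120, 0.01)  # continuous-time artifact, 100x grid
        burst_hi = np.sin(2 * np.pi * t_hi / 9.0) * np.exp(-(((t_hi - 40) / 25) ** 2))
        n_ep, length = 30, 120
        data = np.zeros((1, n_ep * 140 + 50))
        events = np.arange(n_ep) * 140 + 10
        for ev in events:
            frac = rng.uniform(-0.45, 0.45)  # sub-sample onset jitter
            pos = (np.arange(length) + frac) * 100
            data[0, ev : ev + length] += 200.0 * np.interp(pos, np.arange(t_hi.size), burst_hi)
        rec = _rec(data)
        plain = aas_correct(
            rec, events, (0, length), TemplateConfig(window=n_ep, robust_exclude=None)
        )
        aligned = aas_correct(
            rec, events, (0, length),
            TemplateConfig(window=n_ep, robust_exclude=None, align=True),
        )
        assert aligned.data.var() < 0.5 * plain.data.var()

    def test_overlapping_epochs_warn_and_truncate(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(1, 400)))
        events = np.array([50, 90, 130, 170])
        with pytest.warns(UserWarning, match="overlap"):
            out = aas_correct(rec, events, (0, 60), TemplateConfig(window=4))
        assert out.n_samples == rec.n_samples


class TestOBS:
    def test_rank3_stack_annihilated(self):
        rng = np.random.default_rng(7)
        basis, _ = np.linalg.qr(rng.normal(size=(120, 3)))
        weights = rng.normal(size=(40, 3))
        weights -= weights.mean(axis=0)  # zero-mean stack: pure residual space
        stack = weights @ basis.T
        out = obs_residual_removal(stack, 3)
        assert np.sqrt((out**2).mean()) < 1e-6 * np.sqrt((stack**2).mean())
        # explicit projection oracle
        demeaned = stack - stack.mean(axis=0)
        _, _, vt = np.linalg.svd(demeaned, full_matrices=False)
        oracle = stack - (demeaned @ vt[:3].T) @ vt[:3]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_zero_components_is_identity(self):
        stack = np.random.default_rng(0).normal(size=(10, 50))
        np.testing.assert_array_equal(obs_residual_removal(stack, 0), stack)

    def test_noise_variance_strictly_reduced(self):
        stack = np.random.default_rng(0).normal(size=(20, 100))
        out = obs_residual_removal(stack, 1)
        assert out.var() < stack.var()

    @pytest.mark.parametrize("n_obs", [1, 3, 5])
    def test_variance_never_increases(self, n_obs):
        stack = np.random.default_rng(n_obs).normal(size=(12, 64))
        assert obs_residual_removal(stack, n_obs).var() <= stack.var() + 1e-12

    def test_too_many_components_raises(self):
        stack = np.zeros((4, 10))
        with pytest.raises(ValueError, match="n_obs"):
            obs_residual_removal(stack, 4)


class TestGradientCorrect:
    def _suppression_db(self, session, corrected):
        """Power at slice-frequency harmonics, raw vs corrected."""
        from scipy.signal import welch

        rate = session.raw.rate
        f0 = slice_frequency(session.cfg.slices_per_volume, session.cfg.tr)
        harmonics = np.arange(1, int(rate / 2 / f0) + 1) * f0
        freqs, p_raw = welch(session.raw.data, fs=rate, nperseg=8192, axis=1)
        _, p_cor = welch(corrected.data, fs=rate, nperseg=8192, axis=1)
        sel = np.zeros(freqs.size, dtype=bool)
        for h in harmonics:
            sel |= np.abs(freqs - h) <= 0.5
        return 10 * np.log10(p_raw[:, sel].sum() / p_cor[:, sel].sum())

    def test_simulated_gradient_suppressed_30db(self):
        from emriclean.core_io import derive_volume_triggers

        session = simulate_session(SimConfig(duration=60.0, seed=21))
        rec = derive_volume_triggers(session.raw, 39)
        out = gradient_correct(rec)
        assert self._suppression_db(session, out) >= 30.0

    def test_zero_gradient_leaves_data_nearly_unchanged(self):
        from emriclean.core_io import derive_volume_triggers

        session = simulate_session(SimConfig(duration=60.0, seed=22, gradient_amp=0.0))
        rec = derive_volume_triggers(session.raw, 39)
        out = gradient_correct(rec)
        # only sliding template noise (~RMS/sqrt(window)) may be injected
        for i in range(rec.n_channels):
            assert np.corrcoef(out.data[i], rec.data[i])[0, 1] >= 0.97

    def test_missing_volume_markers_raises(self):
        rec = _rec(np.zeros((2, 1000)))
        with pytest.raises(ValueError, match="derive_volume_triggers"):
            gradient_correct(rec)


class TestBCGCorrect:
    def _locked_rms(self, data, peaks, length):
        epochs = [data[:, p : p + length] for p in peaks if p + length <= data.shape[1]]
        return np.sqrt((np.mean(epochs, axis=0) ** 2).mean())

    def _session(self, **kw):
        cfg = SimConfig(
            duration=60.0,
            seed=23,
            gradient_amp=0.0,
            blink_amp=0.0,
            saccade_amp=0.0,
            muscle_amp=0.0,
            pop_amp=0.0,
            motion_amp=0.0,
            bad_channel=None,
            **kw,
        )
        session = simulate_session(cfg)
        rec = downsample(session.raw, 250.0)
        peaks = np.round(np.asarray(session.truth["r_peaks"]) / 20).astype(int)
        return session, rec, peaks

    def test_zero_jitter_bcg_reduced_to_5pct(self):
        _, rec, peaks = self._session(
            hr_jitter=0.0, bcg_amp_jitter=0.0, bcg_latency_jitter_s=0.0
        )
        out = bcg_correct(rec, peaks, TemplateConfig(window=21, robust_exclude=None))
        length = int(np.median(np.diff(peaks)))
        raw_locked = self._locked_rms(rec.data, peaks, length)
        cor_locked = self._locked_rms(out.data, peaks, length)
        assert cor_locked <= 0.05 * raw_locked

    def test_jittered_bcg_locked_rms_strictly_reduced(self):
        _, rec, peaks = self._session()
        out = bcg_correct(rec, peaks)
        length = int(np.median(np.diff(peaks)))
        assert self._locked_rms(out.data, peaks, length) < self._locked_rms(
            rec.data, peaks, length
        )

    def test_zero_bcg_output_highly_correlated_with_input(self):
        """With no artifact the only change is ~RMS/sqrt(21) template noise,
        so per-channel correlation stays above the analytic 1/sqrt(1+1/21)
        floor (~0.977)."""
        _, rec, peaks = self._session(bcg_amp=0.0)
        out = bcg_correct(rec, peaks)
        for i in range(rec.n_channels):
            assert np.corrcoef(out.data[i], rec.data[i])[0, 1] >= 0.97

    def test_too_few_events_raises(self):
        rec = _rec(np.zeros((1, 5000)))
        with pytest.raises(ValueError, match="too few cardiac events"):
            bcg_correct(rec, np.array([100, 400]), TemplateConfig(window=21))

    def test_implausible_rr_raises(self):
        rec = _rec(np.zeros((1, 5000)))
        peaks = np.arange(20) * 10  # 25 bpm equivalent at 250 S/s? -> 0.04 s RR
        with pytest.raises(ValueError, match="cardiac detection failed"):
            bcg_correct(rec, peaks, TemplateConfig(window=4))


class TestDownsample:
    def test_length_arithmetic(self):
        rec = _rec(np.zeros((2, 300000)), rate=5000.0)
        out = downsample(rec, 250.0)
        assert out.n_samples == 15000
        assert out.rate == 250.0

    def test_sample_interval_is_4_ms(self):
        rec = _rec(np.zeros((1, 5000)), rate=5000.0)
        assert 1.0 / downsample(rec, 250.0).rate == pytest.approx(0.004)

    def test_sine_amplitude_preserved(self):
        t = np.arange(300000) / 5000.0
        rec = _rec(np.sin(2 * np.pi * 10 * t), rate=5000.0)
        out = downsample(rec, 250.0)
        mid = out.data[0, 1000:-1000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_antialiasing(self):
        """Content entirely above the target Nyquist must not fold back:
        after decimation its power is >= 40 dB below its original level."""
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(0)
        sos = butter(8, 150.0, btype="high", fs=5000.0, output="sos")
        hf = sosfiltfilt(sos, rng.normal(size=500000))
        out = downsample(_rec(hf, rate=5000.0), 250.0)
        assert 10 * np.log10(out.data.var() / hf.var()) < -40.0

    def test_marker_rescaling_round_half_down(self):
        rec = _rec(
            np.zeros((1, 10000)),
            rate=5000.0,
            markers=[Marker("R128", 30, "slice"), Marker("R128", 50, "slice")],
        )
        out = downsample(rec, 250.0)
        # 30/20 = 1.5 rounds half-down to 1; 50/20 = 2.5 -> 2
        assert list(out.marker_samples("slice")) == [1, 2]

    def test_upsampling_rejected(self):
        rec = _rec(np.zeros((1, 100)), rate=250.0)
        with pytest.raises(ValueError):
            downsample(rec, 500.0)


class TestFilters:
    def _sine(self, freq, rate=250.0, seconds=60.0):
        t = np.arange(int(rate * seconds)) / rate
        return _rec(np.sin(2 * np.pi * freq * t), rate=rate)

    def _plan(self):
        return FilterPlan(band=(1.0, 70.0), notches=[19.5, 26.0, 39.0, 58.5, 60.0])

    @pytest.mark.parametrize("notch", [19.5, 26.0, 39.0, 58.5, 60.0])
    def test_notch_attenuation_30db(self, notch):
        out = apply_filters(self._sine(notch), self._plan())
        rms = np.sqrt((out.data[0, 2000:-2000] ** 2).mean())
        assert rms <= 0.032 / np.sqrt(2) + 1e-12  # >= 30 dB below unit sine

    def test_passband_ripple_below_half_db(self):
        out = apply_filters(self._sine(10.0), self._plan())
        rms = np.sqrt((out.data[0, 2000:-2000] ** 2).mean())
        assert abs(20 * np.log10(rms / (1 / np.sqrt(2)))) <= 0.5

    def test_dc_removed(self):
        rec = _rec(np.full(15000, 100.0))
        out = apply_filters(rec, FilterPlan(band=(1.0, 70.0)))
        assert np.abs(out.data).mean() < 1.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = _rec(rng.normal(size=15000))
        y = _rec(rng.normal(size=15000))
        plan = self._plan()
        lhs = apply_filters(_rec(2.0 * x.data[0] + 3.0 * y.data[0]), plan).data
        rhs = 2.0 * apply_filters(x, plan).data + 3.0 * apply_filters(y, plan).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_notch_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(self._sine(10.0), FilterPlan(band=(1, 70), notches=[125.0]))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterPlan(band=(70.0, 1.0)).validate(250.0)


class TestSliceFrequency:
    def test_study_parameters(self):
        assert slice_frequency(39, 2.0) == pytest.approx(19.5)

    def test_harmonics_below_high_edge(self):
        assert slice_notches(39, 2.0, 70.0) == pytest.approx([19.5, 39.0, 58.5])

    def test_unit_case(self):
        assert slice_frequency(1, 1.0) == 1.0

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            slice_frequency(0, 2.0)
        with pytest.raises(ValueError):
            slice_frequency(39, 0.0)
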