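"""Filtering, delay alignment and beat averaging."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from aortastress import mechanics, preprocessing, synthetic
from aortastress.containers import PressureRadiusSeries

FS = 870.0


def _tone_series(freq, n_seconds=10.0, fs=FS):
    t = np.arange(int(n_seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return PressureRadiusSeries(
        time=t,
        pressure=10_000 + 1_000 * x,
        radius=0.01 + 0.001 * x,
        sampling_rate=fs,
    )


def _tone_amplitude(series_values, freq, t):
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, series_values - series_values.mean(), rcond=None)
    return float(np.hypot(*coef))


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        t = np.arange(2000) / FS
        series = PressureRadiusSeries(
            time=t,
            pressure=np.full(t.size, 12_345.0),
            radius=np.full(t.size, 0.009),
            sampling_rate=FS,
        )
        out = preprocessing.lowpass_filter(series)
        np.testing.assert_allclose(out.pressure, series.pressure, rtol=1e-9)
        np.testing.assert_allclose(out.radius, series.radius, rtol=1e-9)

    @pytest.mark.parametrize("freq", [0.5, 100.0])
    def test_gain_matches_squared_butterworth_magnitude(self, freq):
        """Zero-phase (two-pass) filtering attenuates a pure tone by the
        squared magnitude of the 4th-order Butterworth response."""
        series = _tone_series(freq)
        out = preprocessing.lowpass_filter(series)
        mid = slice(int(3 * FS), int(7 * FS))
        measured = _tone_amplitude(out.pressure[mid], freq, series.time[mid]) / 1_000
        sos = signal.butter(4, 15.0, fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
        predicted = float(np.abs(h[0]) ** 2)
        assert measured == pytest.approx(predicted, rel=0.01, abs=1e-9)
        if freq < 15.0:
            assert measured == pytest.approx(1.0, rel=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocessing.lowpass_filter(_tone_series(1.0), cutoff=500.0)


class TestAlignChannels:
    def test_already_aligned_loop_keeps_zero_lag(self):
        spec = synthetic.representative_subject("male")
        series = synthetic.generate_subject_series(spec)
        out = preprocessing.align_channels(series)
        assert out.delay_corrected_samples == 0

    def test_recovers_constructed_delay(self):
        spec = synthetic.representative_subject("male", delay_samples=23)
        series = synthetic.generate_subject_series(spec)
        out = preprocessing.align_channels(series)
        assert out.delay_corrected_samples == 23

    def test_constant_channel_warns_and_keeps_zero_lag(self):
        t = np.arange(4000) / FS
        series = PressureRadiusSeries(
            time=t,
            pressure=np.full(t.size, 10_000.0),
            radius=0.009 + 0.001 * np.sin(2 * np.pi * t),
            sampling_rate=FS,
        )
        with pytest.warns(RuntimeWarning, match="constant channel"):
            out = preprocessing.align_channels(series)
        assert out.delay_corrected_samples == 0

    def test_half_period_tie_breaks_toward_smaller_lag(self):
        # 5 Hz sinusoid delayed by half a period: +-87 samples correlate
        # equally; the documented rule picks the smaller |lag| and, on an
        # exact tie in |lag|, the earlier (negative) one.
        freq = 5.0
        half_period = int(FS / freq / 2)  # 87 samples
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        delayed = np.roll(x, half_period)
        series = PressureRadiusSeries(
            time=t,
            pressure=10_000 + 1_000 * delayed,
            radius=0.01 + 0.001 * x,
            sampling_rate=FS,
        )
        out = preprocessing.align_channels(series, max_lag=0.12)
        assert abs(out.delay_corrected_samples) == half_period
        assert out.delay_corrected_samples == -half_period


class TestSegmentAndAverage:
    def test_identical_beats_average_to_single_beat(self):
        """With zero noise every beat is identical; the averaged loop must
        match a directly sampled beat within interpolation error."""
        spec = synthetic.representative_subject("male")
        series = synthetic.generate_subject_series(spec)
        loop = preprocessing.segment_and_average(series, n_grid=100)
        phase = np.linspace(0.0, 1.0, 100)
        area = mechanics.area_from_age(spec.age, spec.sex)
        r_ref = spec.r_dias + (spec.r_sys - spec.r_dias) * synthetic.pulse_waveform(phase)
        p_ref = mechanics.pressure_from_radius(r_ref, spec.kappa_true, area)
        assert np.max(np.abs(loop.radius - r_ref) / r_ref) < 1e-3
        assert np.max(np.abs(loop.pressure - p_ref) / p_ref) < 1e-3

    def test_output_length_contract(self):
        spec = synthetic.representative_subject("male")
        series = synthetic.generate_subject_series(spec)
        loop = preprocessing.segment_and_average(series, n_grid=100)
        assert loop.n_samples == 100
        assert loop.radius.size == 100

    def test_averaging_beats_noise(self):
        """Averaging 20 noisy beats gets closer (RMS) to the clean beat
        than any individual noisy beat."""
        spec = dataclasses.replace(
            synthetic.representative_subject("male", seed=5),
            noise_radius_rel=0.01,
            n_beats=22,
        )
        series = synthetic.generate_subject_series(spec)
        loop = preprocessing.segment_and_average(series, n_grid=100)
        phase = np.linspace(0.0, 1.0, 100)
        r_ref = spec.r_dias + (spec.r_sys - spec.r_dias) * synthetic.pulse_waveform(phase)
        rms_avg = np.sqrt(np.mean((loop.radius - r_ref) ** 2))
        feet = preprocessing._diastolic_feet(series.pressure, FS, 0.4, 25.0)
        single_rms = []
        for k in range(feet.size - 1):
            i0, i1 = feet[k], feet[k + 1]
            local = (series.time[i0 : i1 + 1] - series.time[i0]) / (
                series.time[i1] - series.time[i0]
            )
            beat = np.interp(phase, local, series.radius[i0 : i1 + 1])
            single_rms.append(np.sqrt(np.mean((beat - r_ref) ** 2)))
        assert rms_avg < min(single_rms)

    def test_too_few_beats_rejected_with_count(self):
        spec = dataclasses.replace(
            synthetic.representative_subject("male"), n_beats=3
        )
        series = synthetic.generate_subject_series(spec)
        # 3 nominal beats leave only 1 complete foot-to-foot interval
        with pytest.raises(ValueError, match=r"only \d+ complete beats"):
            preprocessing.segment_and_average(series)


class TestPipelineInvariants:
    def test_preprocessing_idempotent_on_clean_loop(self):
        """Re-filtering and re-averaging a series rebuilt from an averaged
        noise-free loop changes values by < 0.1%."""
        spec = synthetic.representative_subject("male")
        series = synthetic.generate_subject_series(spec)
        pre = preprocessing.LoopPreprocessor()
        loop1 = pre.transform(series)
        # tile the averaged loop back into a multi-beat series
        n_rep = 8
        p = np.tile(loop1.pressure[:-1], n_rep)
        r = np.tile(loop1.radius[:-1], n_rep)
        fs = float(loop1.n_samples - 1)  # keep the 1 s beat duration
        t = np.arange(p.size) / fs
        rebuilt = PressureRadiusSeries(
            time=t, pressure=p, radius=r, sampling_rate=fs, subject=series.subject
        )
        loop2 = pre.transform(rebuilt)
        assert np.max(np.abs(loop2.pressure - loop1.pressure) / loop1.pressure) < 1e-3
        assert np.max(np.abs(loop2.radius - loop1.radius) / loop1.radius) < 1e-3

    def test_extrema_of_average_lie_within_raw_range(self):
        spec = synthetic.representative_subject(
            "male", noise_radius_rel=0.01, noise_pressure_rel=0.01, seed=3
        )
        series = synthetic.generate_subject_series(spec)
        loop = preprocessing.LoopPreprocessor().transform(series)
        assert series.pressure.min() <= loop.pressure.min()
        assert loop.pressure.max() <= series.pressure.max()
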