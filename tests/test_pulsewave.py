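"""Kasai estimation, pulse unmixing, and cardiovascular statistics."""

import numpy as np
import pytest

from rcflow import VoxelGrid, make_ecg_trace
from rcflow.beamform import IQVolumeSeries
from rcflow.pulsewave import (
    PulseWaveTrace,
    bland_altman,
    detect_pulse_peaks,
    extract_pulse_component,
    heart_rate,
    kasai_phase_shift,
    peak_fwhm,
    pwtt,
    pwv,
)

F0, C = 9.02e6, 1480.0


def _iq_from_displacement(disp_t, n=(6, 6, 6), framerate=500.0, seed=0, amp_noise=0.0):
    """IQ series of a uniformly translating medium: phase 4 pi f0 d(t) / c."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n) + 1j * rng.normal(size=n)
    phase = 4 * np.pi * F0 * np.asarray(disp_t) / C
    data = base[..., None] * np.exp(1j * phase)
    if amp_noise:
        data = data + amp_noise * (rng.normal(size=data.shape) + 1j * rng.normal(size=data.shape))
    ax = np.arange(n[0]) * 80e-6
    grid = VoxelGrid(ax, ax, ax + 1e-3)
    return IQVolumeSeries(data, grid, framerate, F0)


class TestKasai:
    def test_uniform_sub_wavelength_motion_recovered_exactly(self):
        """Criterion: axial velocities below lambda/8 per frame recover to < 0.1%."""
        framerate = 500.0
        lam = C / F0
        for frac in (0.01, 0.05, 0.12):  # displacement per frame in wavelengths
            d_frame = frac * lam
            disp = d_frame * np.arange(100)
            series = _iq_from_displacement(disp, framerate=framerate)
            v = kasai_phase_shift(series)
            v_true = d_frame * framerate
            assert np.abs(v - v_true).max() < 1e-3 * v_true

    def test_example_phase_to_velocity_mapping(self):
        # phase pi/2 per frame at 1 kHz framerate -> ~20.5 mm/s
        framerate = 1000.0
        d_frame = (np.pi / 2) * C / (4 * np.pi * F0)
        disp = d_frame * np.arange(50)
        v = kasai_phase_shift(_iq_from_displacement(disp, framerate=framerate))
        assert v.mean() == pytest.approx(20.5e-3, rel=0.01)

    def test_motion_beyond_quarter_wavelength_wraps(self):
        framerate = 500.0
        lam = C / F0
        d_frame = 0.3 * lam  # beyond lambda/4: aliased
        disp = d_frame * np.arange(60)
        v = kasai_phase_shift(_iq_from_displacement(disp, framerate=framerate))
        v_true = d_frame * framerate
        assert np.abs(v.mean() - v_true) > 0.1 * v_true

    def test_output_length_is_n_minus_one(self):
        series = _iq_from_displacement(np.zeros(40))
        assert kasai_phase_shift(series).shape[-1] == 39


def _pulse_pattern(t, period=1.0, width=0.08):
    """Sharp positive deflection once per cardiac cycle."""
    ph = np.mod(t, period)
    return np.exp(-0.5 * ((ph - 3 * width) / width) ** 2)


class TestExtractPulseComponent:
    def _mixed_series(self, seed=0, n_slow=600, framerate=100.0):
        """Cardiac pulse + two motion artifacts (breathing-like sinusoid, drift)."""
        rng = np.random.default_rng(seed)
        t = np.arange(n_slow) / framerate
        pulse = _pulse_pattern(t)
        breathing = 0.5 * np.sin(2 * np.pi * 0.08 * t)
        drift = 0.3 * t / t[-1]
        maps = rng.normal(size=(3, 6, 6, 6))
        x = maps[0][..., None] * pulse + maps[1][..., None] * breathing + maps[2][..., None] * drift
        x = x + 0.01 * rng.normal(size=x.shape)
        return x, pulse, framerate

    def test_recovers_cardiac_source_from_artifact_mixture(self):
        x, pulse, fr = self._mixed_series()
        trace, diag = extract_pulse_component(x, fr, seed=0)
        r = np.corrcoef(trace.values, pulse)[0, 1]
        assert abs(r) > 0.95

    def test_seeded_unmixing_is_reproducible(self):
        x, _, fr = self._mixed_series(seed=3)
        a, _ = extract_pulse_component(x, fr, seed=5)
        b, _ = extract_pulse_component(x, fr, seed=5)
        assert np.allclose(a.values, b.values)

    def test_no_cardiac_content_raises(self):
        rng = np.random.default_rng(0)
        t = np.arange(600) / 100.0
        slow = np.sin(2 * np.pi * 0.03 * t)
        x = rng.normal(size=(4, 4, 4))[..., None] * slow
        with pytest.raises(ValueError, match="no pulse detected"):
            extract_pulse_component(x, 100.0, seed=0)


class TestPeaksAndRates:
    def test_noiseless_60bpm_peaks_at_one_second(self):
        fr = 250.0
        t = np.arange(int(10 * fr)) / fr
        trace = PulseWaveTrace(_pulse_pattern(t), fr)
        peaks = detect_pulse_peaks(trace)
        assert len(peaks) == 10
        assert np.allclose(np.diff(peaks), 1.0, atol=1 / fr)
        assert np.allclose(heart_rate(peaks), 60.0, atol=0.5)

    def test_flat_trace_gives_no_peaks(self):
        trace = PulseWaveTrace(np.zeros(1000), 100.0)
        assert len(detect_pulse_peaks(trace)) == 0

    def test_generated_beat_count_recovered(self):
        ecg = make_ecg_trace(hr_bpm=72, duration=30, hrv_sd_bpm=3, seed=2)
        fr = 200.0
        t = np.arange(int(30 * fr)) / fr
        sig = np.zeros_like(t)
        for rp in ecg.r_peak_times:
            sig += np.exp(-0.5 * ((t - rp - 0.2) / 0.03) ** 2)
        peaks = detect_pulse_peaks(PulseWaveTrace(sig, fr))
        expected = np.sum(ecg.r_peak_times + 0.2 <= t[-1])
        assert len(peaks) == expected

    def test_heart_rate_requires_two_peaks(self):
        with pytest.raises(ValueError):
            heart_rate([1.0])


class TestBlandAltman:
    def test_identical_and_offset_series(self):
        a = np.array([60.0, 62.0, 61.0, 63.0])
        ba = bland_altman(a, a)
        assert ba.bias == 0 and ba.loa_low == 0 and ba.loa_high == 0
        ba2 = bland_altman(a + 1.5, a)
        assert ba2.bias == pytest.approx(1.5)
        assert ba2.loa_high - ba2.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_loa_half_width_from_difference_sd(self):
        rng = np.random.default_rng(0)
        a = 60 + rng.normal(0, 2, 4000)
        b = a + rng.normal(0, 0.87, 4000)
        ba = bland_altman(b, a)
        assert (ba.loa_high - ba.bias) == pytest.approx(1.96 * 0.87, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bland_altman(np.ones(3), np.ones(4))


class TestTransitTime:
    def test_constant_delay_recovered(self):
        delays, mean, sd, dropped = pwtt([0.0, 1.0], [0.214, 1.214])
        assert np.allclose(delays, 0.214) and dropped == 0
        assert mean == pytest.approx(0.214)

    def test_identical_trains_give_zero(self):
        delays, mean, _, _ = pwtt([0, 1, 2], [0, 1, 2])
        assert mean == 0.0

    def test_missing_beat_dropped(self):
        r = [0.0, 1.0, 2.0]
        m = [0.2, 2.2, 2.9]  # 2.9 is 0.9 s after the last R-peak: unmatched
        delays, _, _, dropped = pwtt(r, m)
        assert len(delays) == 2 and dropped == 1

    def test_pwv_worked_example(self):
        assert pwv(0.88, 0.214) == pytest.approx(4.11, abs=0.005)
        assert pwv(1.0, 1.0) == 1.0
        assert pwv(1.76, 0.214) == pytest.approx(2 * pwv(0.88, 0.214))

    def test_pwv_rejects_non_positive(self):
        with pytest.raises(ValueError):
            pwv(0.0, 0.2)


class TestPeakWidth:
    def test_gaussian_pulse_fwhm(self):
        fr = 1000.0
        t = np.arange(int(3 * fr)) / fr
        sigma = 0.0276  # 2.355 sigma = 65 ms
        sig = sum(np.exp(-0.5 * ((t - c) / sigma) ** 2) for c in (0.5, 1.5, 2.5))
        trace = PulseWaveTrace(sig, fr)
        widths = peak_fwhm(trace)
        assert np.allclose(widths, 0.065, atol=0.003)

    def test_triangle_half_base_and_amplitude_invariance(self):
        fr = 1000.0
        t = np.arange(int(2 * fr)) / fr
        base = 0.2
        sig = np.clip(1 - np.abs(t - 1.0) / (base / 2), 0, None)
        w1 = peak_fwhm(PulseWaveTrace(sig, fr))
        w2 = peak_fwhm(PulseWaveTrace(5 * sig, fr))
        assert w1[0] == pytest.approx(base / 2, rel=0.02)
        assert np.allclose(w1, w2)
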