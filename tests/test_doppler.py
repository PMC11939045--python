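"""Clutter filtering, Doppler products and the resistive index."""

import numpy as np
import pytest

from rcflow import VoxelGrid
from rcflow.beamform import IQVolumeSeries, bmode
from rcflow.doppler import (
    ClutterFilterSpec,
    fit_skin_surface,
    power_doppler,
    resistive_index,
    signed_power_doppler,
    spectral_doppler,
    svd_clutter_filter,
)
from rcflow.phantoms import PulsatileWaveform


def _series(data, framerate=1000.0, f0=9.02e6):
    n = data.shape[0]
    ax = np.arange(n) * 80e-6
    grid = VoxelGrid(ax, ax, ax + 1e-3)
    return IQVolumeSeries(data, grid, framerate, f0)


def _doppler_series(v_axial, n=(8, 8, 8), n_slow=128, framerate=1000.0, f0=9.02e6, c=1480.0, noise=0.0, seed=0):
    """IQ cube whose slow-time phase advances as axial motion at v (m/s)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n) + 1j * rng.normal(size=n)
    t = np.arange(n_slow)
    phase = 4 * np.pi * f0 * v_axial / (c * framerate) * t
    data = base[..., None] * np.exp(1j * phase)
    if noise:
        data = data + noise * (rng.normal(size=data.shape) + 1j * rng.normal(size=data.shape))
    return _series(data, framerate, f0)


class TestClutterFilterSpec:
    def test_mode_range_for_200_frames(self):
        # in vivo rule: first 15% (30 modes of 200) and last 50 modes removed
        assert ClutterFilterSpec().mode_range(200) == (30, 150)

    def test_too_short_ensemble_names_minimum(self):
        s = _series(np.ones((4, 4, 4, 40), complex))
        with pytest.raises(ValueError, match="ensemble too short"):
            svd_clutter_filter(s)


class TestSvdClutterFilter:
    def test_static_signal_fully_removed(self):
        rng = np.random.default_rng(0)
        static = rng.normal(size=(6, 6, 6, 1)) * np.ones((1, 1, 1, 100))
        s = _series(static.astype(complex))
        filt, sv = svd_clutter_filter(s, ClutterFilterSpec(0.15, 20))
        assert np.abs(filt.data).max() < 1e-10 * np.abs(s.data).max()
        # static ensemble is rank one
        assert sv[1] < 1e-10 * sv[0]

    def test_filter_is_an_orthogonal_projection(self, tube_run):
        """The filter projects onto the kept temporal subspace: re-projecting
        the output onto that subspace changes nothing, and the removed part is
        orthogonal to it."""
        series = tube_run["series"]
        filt, _ = svd_clutter_filter(series)
        cas = series.casorati()
        _, _, vh = np.linalg.svd(cas, full_matrices=False)
        lo, hi = ClutterFilterSpec().mode_range(series.n_slow)
        P = vh[lo:hi].conj().T @ vh[lo:hi]  # projector onto kept temporal modes
        out = filt.casorati()
        scale = np.abs(out).max()
        assert np.abs(out @ P - out).max() < 1e-8 * scale
        removed = cas - out
        assert np.abs(removed @ P).max() < 1e-8 * np.abs(cas).max()

    def test_vessel_dominates_background_after_filtering(self, tube_run):
        filt, _ = svd_clutter_filter(tube_run["series"])
        pd = power_doppler(filt)
        mask = tube_run["flow_mask"]
        assert pd[mask].mean() > 5 * pd[~mask].mean()


class TestPowerDoppler:
    def test_zero_input_and_quadratic_scaling(self):
        s = _series(np.zeros((4, 4, 4, 8), complex))
        assert np.all(power_doppler(s) == 0)
        d = _doppler_series(0.002)
        assert np.allclose(power_doppler(_series(3 * d.data)), 9 * power_doppler(d))

    def test_invariant_to_global_phase_rotation(self):
        d = _doppler_series(0.001)
        rotated = _series(d.data * np.exp(1j * 1.234))
        assert np.allclose(power_doppler(rotated), power_doppler(d))


class TestSignedPowerDoppler:
    def test_sign_follows_flow_direction(self):
        # positive axial velocity advances the slow-time phase: positive sign
        up = _doppler_series(+0.003)
        down = _doppler_series(-0.003)
        assert np.all(signed_power_doppler(up) > 0)
        assert np.all(signed_power_doppler(down) < 0)
        assert np.allclose(np.abs(signed_power_doppler(down)), power_doppler(down))


class TestSpectralDoppler:
    def test_ridge_at_known_velocity(self):
        v = 0.004
        s = _doppler_series(v, n_slow=256, noise=0.05)
        sd = spectral_doppler(s, (4, 4, 4))
        ridge = sd.velocity[np.argmax(sd.magnitude.mean(axis=1))]
        bin_width = np.diff(sd.velocity).mean()
        assert ridge == pytest.approx(v, abs=1.5 * bin_width)

    def test_aliasing_beyond_nyquist_velocity(self):
        f0, fr, c = 9.02e6, 1000.0, 1480.0
        v_nyq = c * fr / (4 * f0)
        v = 1.5 * v_nyq
        sd = spectral_doppler(_doppler_series(v, n_slow=256), (4, 4, 4))
        ridge = sd.velocity[np.argmax(sd.magnitude.mean(axis=1))]
        assert ridge == pytest.approx(v - 2 * v_nyq, abs=2 * np.diff(sd.velocity).mean())

    def test_roi_outside_grid_rejected(self):
        s = _doppler_series(0.001)
        with pytest.raises(ValueError, match="ROI"):
            spectral_doppler(s, (0, 4, 4))

    def test_parseval_power_consistency(self):
        from scipy.signal.windows import hann

        # uniform ROI so the ROI-averaged magnitude is the per-voxel magnitude
        n_slow, fr = 240, 1000.0
        phase = 4 * np.pi * 9.02e6 * 0.002 / (1480.0 * fr) * np.arange(n_slow)
        data = np.broadcast_to(np.exp(1j * phase), (8, 8, 8, n_slow)).copy()
        s = _series(data, fr)
        sd = spectral_doppler(s, (4, 4, 4))
        w = hann(30, sym=False)
        factor = 30 * (w**2).sum()  # DFT Parseval x window energy
        mid = sd.magnitude.shape[1] // 2
        spec_power = (sd.magnitude[:, mid] ** 2).sum() / factor
        roi_pd = power_doppler(s)[3:6, 3:6, 3:6].mean()
        assert spec_power == pytest.approx(roi_pd, rel=0.05)


class TestResistiveIndex:
    def test_closed_form_and_constant_flow(self):
        t = np.linspace(0, 4, 1000)
        v = 7.5 + 2.5 * np.cos(2 * np.pi * t)  # peak 10, trough 5
        assert resistive_index(v, framerate_hz=250.0) == pytest.approx(0.5, abs=0.01)
        assert resistive_index(np.full(100, 3.0), framerate_hz=100.0) == 0.0

    def test_generator_waveform_round_trip(self):
        wf = PulsatileWaveform(resistive_index=0.57)
        t = np.arange(0, 4 * wf.period_s, 1 / 250)
        v = wf.value(t)
        assert resistive_index(v, framerate_hz=250.0) == pytest.approx(0.57, abs=0.02)

    def test_non_positive_peak_rejected(self):
        with pytest.raises(ValueError):
            resistive_index(-np.ones(100), framerate_hz=100.0)


class TestSkinSurface:
    def _volume_with_interface(self, z0_vox=10, nx=12, nz=30, tilt=0.0):
        ax = np.arange(nx) * 100e-6
        z = np.arange(nz) * 50e-6
        grid = VoxelGrid(ax, ax, z)
        vol = np.full((nx, nx, nz), -60.0)
        for i in range(nx):
            k = int(z0_vox + tilt * i)
            vol[i, :, k:] = 0.0
        return vol, grid, z[z0_vox]

    def test_flat_interface_recovered(self):
        vol, grid, z0 = self._volume_with_interface()
        surface, mask = fit_skin_surface(vol, grid, poly_order=2)
        assert np.all(np.abs(surface - z0) <= grid.spacing[2] + 1e-12)
        # masked region lies above the surface and would zero any Doppler product
        assert not mask[:, :, :9].any() and mask[:, :, 12:].all()

    def test_order_zero_on_tilted_interface_gives_mean_plane(self):
        vol, grid, z0 = self._volume_with_interface(tilt=0.5)
        surface, _ = fit_skin_surface(vol, grid, poly_order=0)
        assert np.ptp(surface) < 1e-12
        zs = [grid.z[int(10 + 0.5 * i)] for i in range(12)]
        assert surface.mean() == pytest.approx(np.mean(zs) + grid.spacing[2], abs=2 * grid.spacing[2])

    def test_degenerate_detection_rejected(self):
        vol = np.full((10, 10, 20), -100.0)
        ax = np.arange(10) * 1e-4
        grid = VoxelGrid(ax, ax, np.arange(20) * 5e-5)
        with pytest.raises(ValueError, match="30%"):
            fit_skin_surface(vol, grid)
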