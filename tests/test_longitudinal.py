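"""Vesselness, segmentation, rigid registration and repeatability analysis."""

import numpy as np
import pytest
from scipy import ndimage

from rcflow.longitudinal import (
    RigidTransform,
    apply_transform,
    common_volume_fraction,
    pearson_corr_volumes,
    register_rigid,
    segment_vessels,
    vesselness,
)

SPACING = (0.1, 0.1, 0.1)  # mm


def _tube_volume(shape=(48, 48, 32), radius=2.0, axis=0, blur=1.0):
    vol = np.zeros(shape)
    c = [s // 2 for s in shape]
    idx = np.indices(shape).astype(float)
    axes = [a for a in range(3) if a != axis]
    r2 = sum((idx[a] - c[a]) ** 2 for a in axes)
    vol[r2 <= radius**2] = 1.0
    return ndimage.gaussian_filter(vol, blur)


def _blob_volume(shape=(48, 48, 32), radius=2.0, blur=1.0):
    vol = np.zeros(shape)
    c = [s // 2 for s in shape]
    idx = np.indices(shape).astype(float)
    r2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
    vol[r2 <= radius**2] = 1.0
    return ndimage.gaussian_filter(vol, blur)


class TestVesselness:
    def test_tube_centerline_response_dominates_background(self):
        vol = _tube_volume()
        resp = vesselness(vol)
        center = resp[10:-10, 24, 16]
        background = np.median(resp[resp > 0]) if (resp > 0).any() else 0.0
        assert center.min() > 5 * max(background, 1e-12)

    def test_tube_beats_blob_at_matched_contrast(self):
        tube = vesselness(_tube_volume())
        blob = vesselness(_blob_volume())
        # compare raw frangi responses before per-volume normalization
        from skimage.filters import frangi

        rt = frangi(_tube_volume(), sigmas=(1, 2, 3), black_ridges=False).max()
        rb = frangi(_blob_volume(), sigmas=(1, 2, 3), black_ridges=False).max()
        assert rt > rb

    def test_constant_volume_all_zero(self):
        assert np.all(vesselness(np.ones((16, 16, 16))) == 0)


class TestSegmentation:
    def test_tube_segmentation_connected_and_monotone(self):
        resp = vesselness(_tube_volume())
        low = segment_vessels(resp, 0.2)
        high = segment_vessels(resp, 0.5)
        assert np.all(high <= low)  # higher threshold is a subset
        lab, n_comp = ndimage.label(low, structure=np.ones((3, 3, 3)))
        counts = np.bincount(lab.ravel())[1:]
        assert counts.max() >= 0.9 * low.sum()  # a single dominant centerline component

    def test_empty_segmentation_raises(self):
        resp = 0.5 * vesselness(_tube_volume())
        with pytest.raises(ValueError, match="empty"):
            segment_vessels(resp, 0.9)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform((5.0, -3.0, 2.0), (0.8, -0.4, 0.3), (2.0, 2.0, 1.5))
        ti = t.inverse()
        comp = t.compose(ti)
        assert np.allclose(comp.rotation_deg, 0, atol=1e-10)
        assert np.allclose(comp.translation_mm, 0, atol=1e-10)

    def test_apply_then_inverse_restores_volume(self):
        vol = _tube_volume()
        center = tuple((np.asarray(vol.shape) - 1) / 2 * SPACING)
        t = RigidTransform((0, 0, 4.0), (0.3, -0.2, 0.1), center)
        out = apply_transform(apply_transform(vol, t, SPACING), t.inverse(), SPACING)
        core = (slice(6, -6),) * 3
        assert np.corrcoef(out[core].ravel(), vol[core].ravel())[0, 1] > 0.99


class TestRegistration:
    def _fixture_volumes(self, rot_z=5.0, shift=(0.8, 0.0, 0.0), noise_db=None, seed=0):
        rng = np.random.default_rng(seed)
        fixed = _tube_volume() + 0.7 * np.roll(_tube_volume(axis=1), 6, axis=2)
        # off-center blobs pin down all three rotation axes
        for p, a in (((10, 14, 8), 0.9), ((34, 30, 22), 0.8), ((20, 38, 10), 0.7)):
            blob = np.zeros(fixed.shape)
            blob[p] = a
            fixed += ndimage.gaussian_filter(blob, 2.0) * 60
        center = tuple((np.asarray(fixed.shape) - 1) / 2 * SPACING)
        t_true = RigidTransform((rot_z, 0, 0), shift, center)
        moving = apply_transform(fixed, t_true, SPACING)
        if noise_db is not None:
            sigma = fixed.std() / 10 ** (noise_db / 20)
            fixed = fixed + sigma * rng.normal(size=fixed.shape)
            moving = moving + sigma * rng.normal(size=moving.shape)
        return moving, fixed, t_true, center

    def test_known_transform_recovered(self):
        """The pullback of a (0.8 mm, 5 deg) motion is recovered within 0.1 mm / 0.5 deg."""
        moving, fixed, t_true, center = self._fixture_volumes(rot_z=5.0, shift=(0.8, 0.0, 0.0))
        t, ok = register_rigid(moving, fixed, SPACING)
        expected = t_true.inverse()
        assert ok
        assert np.allclose(t.translation_mm, expected.translation_mm, atol=0.1)
        assert np.allclose(t.rotation_deg, expected.rotation_deg, atol=0.5)

    def test_recovery_under_noise_grid(self):
        """Vesselness-driven registration survives 10-dB noise over a grid of motions.

        Mirrors the segmentation-first pipeline: the similarity metric runs on
        the vesselness-enhanced volumes, not the raw noisy ones."""
        for rot, shift, seed in [(-4.0, (0.5, -0.6, 0.2), 1), (6.0, (-1.0, 0.3, 0.0), 2)]:
            moving, fixed, t_true, _ = self._fixture_volumes(rot_z=rot, shift=shift, noise_db=10.0, seed=seed)
            t, ok = register_rigid(vesselness(moving), vesselness(fixed), SPACING)
            expected = t_true.inverse()
            assert ok
            assert np.allclose(t.translation_mm, expected.translation_mm, atol=0.1)
            assert np.allclose(t.rotation_deg, expected.rotation_deg, atol=0.5)

    def test_identity_for_identical_volumes(self):
        vol = _tube_volume() + 0.7 * np.roll(_tube_volume(axis=1), 6, axis=2)
        t, ok = register_rigid(vol, vol, SPACING)
        assert ok
        assert np.allclose(t.translation_mm, 0, atol=0.02)
        assert np.allclose(t.rotation_deg, 0, atol=0.1)

    def test_unrelated_noise_flags_non_convergence(self):
        rng = np.random.default_rng(0)
        a = np.abs(rng.normal(size=(24, 24, 16)))
        b = np.abs(rng.normal(size=(24, 24, 16)))
        t, ok = register_rigid(a, b, SPACING)
        assert not ok


class TestCorrelationAndOverlap:
    def test_pearson_trivial_cases(self):
        a = _tube_volume()
        assert pearson_corr_volumes(a, a) == pytest.approx(1.0)
        assert pearson_corr_volumes(a, -a + 3.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="variance"):
            pearson_corr_volumes(a, np.zeros_like(a))

    def test_registration_raises_repeat_scan_correlation(self):
        rng = np.random.default_rng(3)
        fixed = _tube_volume() + 0.7 * np.roll(_tube_volume(axis=1), 6, axis=2)
        center = tuple((np.asarray(fixed.shape) - 1) / 2 * SPACING)
        t_true = RigidTransform((4.0, 0, 0), (0.6, -0.4, 0.0), center)
        moving = apply_transform(fixed, t_true, SPACING) + 0.05 * rng.normal(size=fixed.shape)
        fixed_n = fixed + 0.05 * rng.normal(size=fixed.shape)
        r_before = pearson_corr_volumes(moving, fixed_n)
        t, ok = register_rigid(moving, fixed_n, SPACING)
        aligned = apply_transform(moving, t, SPACING)
        r_after = pearson_corr_volumes(aligned, fixed_n)
        assert ok and r_after > r_before + 0.1

    def test_common_volume_fraction_cases(self):
        fov = (9.6, 9.6, 9.6)
        center = tuple(f / 2 for f in fov)
        assert common_volume_fraction(RigidTransform(center_mm=center), fov) == pytest.approx(1.0)
        t = RigidTransform((0, 0, 0), (0.83, 0, 0), center)
        assert common_volume_fraction(t, fov) == pytest.approx((9.6 - 0.83) / 9.6, abs=0.02)
        tr = RigidTransform((4.0, 2.0, -3.0), (0.5, -0.2, 0.1), center)
        assert common_volume_fraction(tr, fov) == pytest.approx(common_volume_fraction(tr.inverse(), fov), abs=0.02)
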