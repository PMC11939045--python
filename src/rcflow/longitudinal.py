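"""Longitudinal analysis of repeated 3-D power-Doppler volumes.

Repositionable-sensor studies re-image the same vascular volume days or
months apart; small placement errors are corrected in software. The chain
is: Hessian-based vesselness enhancement of the power-Doppler volume,
threshold segmentation, 6-DOF rigid registration of the vesselness volumes
(normalized cross-correlation, multi-resolution Powell search), and Pearson
correlation of the aligned volumes as the repeatability figure.

Transforms use ZYX Euler angles (degrees) about the volume center, with
translations in millimeters; this convention is serialized with every
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from skimage.filters import frangi

__all__ = [
    "RigidTransform",
    "vesselness",
    "segment_vessels",
    "register_rigid",
    "apply_transform",
    "pearson_corr_volumes",
    "common_volume_fraction",
]


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: ZYX Euler angles (deg) about the volume center.

    The transform maps fixed-volume coordinates (mm) to moving-volume
    coordinates: ``p_mov = R (p_fix - center) + center + translation``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rotation_deg, degrees=True).as_matrix()

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (both about self's center)."""
        ra, rb = self.matrix(), other.matrix()
        r = ra @ rb
        c = np.asarray(self.center_mm)
        t = ra @ (np.asarray(other.translation_mm)) + np.asarray(self.translation_mm)
        ang = Rotation.from_matrix(r).as_euler("ZYX", degrees=True)
        return RigidTransform(tuple(ang), tuple(t), tuple(c))

    def inverse(self) -> "RigidTransform":
        r = self.matrix().T
        t = -r @ np.asarray(self.translation_mm)
        ang = Rotation.from_matrix(r).as_euler("ZYX", degrees=True)
        return RigidTransform(tuple(ang), tuple(t), self.center_mm)

    def as_params(self) -> np.ndarray:
        return np.concatenate([self.rotation_deg, self.translation_mm])

    @classmethod
    def from_params(cls, p: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(tuple(p[:3]), tuple(p[3:6]), tuple(center_mm))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": "ZYX-euler-about-center",
        }


def vesselness(pd: np.ndarray, scales_vox: tuple[float, ...] = (1.0, 2.0, 3.0)) -> np.ndarray:
    """Multi-scale Hessian tubularity of bright vessels, normalized to [0, 1].

    Thin wrapper over the Frangi filter evaluated at the given Gaussian
    scales (voxels); the maximum response over scales is kept. A constant
    volume returns all zeros.
    """
    if len(scales_vox) < 1:
        raise ValueError("need at least one scale")
    pd = np.asarray(pd, float)
    if np.ptp(pd) == 0:
        return np.zeros_like(pd)
    resp = frangi(pd, sigmas=scales_vox, black_ridges=False)
    m = resp.max()
    return resp / m if m > 0 else resp


def segment_vessels(response: np.ndarray, threshold: float = 0.1, min_voxels: int = 27) -> np.ndarray:
    """Binary vessel mask: response > threshold, small components removed."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    mask = response > threshold
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    counts = np.bincount(lab.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    mask = keep[lab]
    if not mask.any():
        raise ValueError("empty segmentation")
    return mask


def _volume_center_mm(shape, spacing_mm) -> np.ndarray:
    return (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing_mm)


def apply_transform(volume: np.ndarray, t: RigidTransform, spacing_mm, order: int = 3) -> np.ndarray:
    """Resample ``volume`` under the rigid transform (spline interpolation).

    The output voxel at physical position p takes the moving volume's value
    at ``t(p)``; linear interpolation (order=1) is used inside optimization,
    cubic for final resampling.
    """
    spacing = np.asarray(spacing_mm, float)
    r = t.matrix()
    c = np.asarray(t.center_mm)
    # voxel index -> mm -> transform -> mm -> voxel index
    a_mm = r
    b_mm = c + np.asarray(t.translation_mm) - r @ c
    a_idx = np.diag(1.0 / spacing) @ a_mm @ np.diag(spacing)
    b_idx = (b_mm) / spacing
    return ndimage.affine_transform(volume, a_idx, offset=b_idx, order=order, mode="constant", cval=0.0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    m = (a != 0) & (b != 0)
    if m.sum() < 10:
        return 0.0
    av, bv = a[m] - a[m].mean(), b[m] - b[m].mean()
    den = np.sqrt((av**2).sum() * (bv**2).sum())
    return float((av * bv).sum() / den) if den > 0 else 0.0


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing_mm,
    init: RigidTransform | None = None,
    smooth_vox: tuple[float, ...] = (2.0, 0.0),
    min_correlation: float = 0.3,
) -> tuple[RigidTransform, bool]:
    """6-DOF rigid alignment of ``moving`` onto ``fixed`` by NCC maximization.

    Returns the *pullback* transform ``t``: resampling the moving volume
    with ``apply_transform(moving, t, spacing)`` aligns it with ``fixed``
    (if the moving volume was generated by motion ``m``, the result is
    ``m.inverse()``). Multi-resolution: Powell search on Gaussian-smoothed
    volumes, refined at full resolution; deterministic for a fixed ``init``.
    The convergence flag is False when the final correlation stays below
    ``min_correlation``; the best-found transform is returned either way.
    """
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share the same grid")
    spacing = np.asarray(spacing_mm, float)
    center = _volume_center_mm(moving.shape, spacing)
    p0 = (init or RigidTransform(center_mm=tuple(center))).as_params()

    def cost_factory(mov, fix):
        def cost(p):
            t = RigidTransform.from_params(p, tuple(center))
            return -_ncc(apply_transform(mov, t, spacing, order=1), fix)

        return cost

    p = p0
    for stage, s in enumerate(smooth_vox):
        mov = ndimage.gaussian_filter(moving, s) if s > 0 else moving
        fix = ndimage.gaussian_filter(fixed, s) if s > 0 else fixed
        # shrinking trust region: wide search at coarse scale, local refinement after
        half = np.array([10.0] * 3 + [2.5] * 3) if stage == 0 else np.array([2.0] * 3 + [0.5] * 3)
        bounds = list(zip(p - half, p + half))
        res = minimize(
            cost_factory(mov, fix),
            p,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 400},
        )
        p = res.x
    final_corr = -cost_factory(moving, fixed)(p)
    t = RigidTransform.from_params(p, tuple(center))
    return t, bool(final_corr >= min_correlation)


def pearson_corr_volumes(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two volumes over a common-support mask."""
    if mask is None:
        mask = np.ones(a.shape, bool)
    if not mask.any():
        raise ValueError("empty mask")
    av, bv = a[mask].astype(float), b[mask].astype(float)
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(av, bv)[0, 1])


def common_volume_fraction(t: RigidTransform, fov_mm: tuple[float, float, float], n: int = 48) -> float:
    """Fraction of the FOV box shared with its transformed copy.

    Evaluated by fine voxelization: sample points of the box, map them
    through ``t``, and count those landing back inside. Symmetric in
    ``t`` vs ``t^{-1}`` up to sampling error.
    """
    fov = np.asarray(fov_mm, float)
    axes = [np.linspace(0, f, n) for f in fov]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    r = t.matrix()
    c = np.asarray(t.center_mm)
    mapped = (pts - c) @ r.T + c + np.asarray(t.translation_mm)
    inside = np.all((mapped >= 0) & (mapped <= fov), axis=1)
    return float(inside.mean())
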