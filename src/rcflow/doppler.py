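"""Slow-time Doppler processing: skin masking, SVD clutter filtering, power,
signed and spectral Doppler, and the resistive index.

The clutter filter follows the acquisition-specific rule used with this
sensor: decompose the Casorati matrix (voxels x slow time), discard the first
15% of the singular modes (tissue) and the last 50 modes (electronic noise),
and reconstruct. Power Doppler is the residual slow-time power per voxel, a
proxy for local blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT, find_peaks
from scipy.signal.windows import hann

from .beamform import IQVolumeSeries

__all__ = [
    "ClutterFilterSpec",
    "SpectralDoppler",
    "fit_skin_surface",
    "svd_clutter_filter",
    "power_doppler",
    "signed_power_doppler",
    "spectral_doppler",
    "resistive_index",
]


@dataclass(frozen=True)
class ClutterFilterSpec:
    """SVD clutter-filter cutoffs.

    The in vivo rule removes the first ``low_fraction`` of the modes (tissue
    spans a subspace that grows with the ensemble) and the last
    ``high_count`` modes (electronic noise). For bench phantoms whose
    clutter is static (rank ~1), set ``low_count`` instead: an absolute
    low-mode cutoff that does not grow with the ensemble, so comparisons
    across acquisition durations see the same blood subspace.
    """

    low_fraction: float = 0.15
    high_count: int = 50
    low_count: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.low_fraction < 1 or self.high_count < 0:
            raise ValueError("invalid clutter filter cutoffs")
        if self.low_count is not None and self.low_count < 0:
            raise ValueError("low_count must be >= 0")

    def mode_range(self, n_slow: int) -> tuple[int, int]:
        """(first kept mode, one-past-last kept mode) for an ensemble length."""
        lo = self.low_count if self.low_count is not None else int(np.ceil(self.low_fraction * n_slow))
        hi = n_slow - self.high_count
        return lo, hi


@dataclass(frozen=True)
class SpectralDoppler:
    """Velocity-resolved slow-time spectrogram of a small ROI."""

    magnitude: np.ndarray  # (n_velocity_bins, n_times)
    velocity: np.ndarray  # m/s, symmetric around 0
    times: np.ndarray  # s
    window: int = 30


def fit_skin_surface(bmode_db: np.ndarray, grid, poly_order: int = 2, gradient_floor_db: float = -40.0):
    """Locate the skin interface and fit a polynomial surface z(x, y).

    The interface is detected per lateral column as the depth of maximum
    axial gradient of the envelope (in dB); columns whose B-mode never rises
    above ``gradient_floor_db`` are ignored. Returns ``(surface_z, mask)``
    where ``mask`` is True below the fitted surface (tissue side); zero the
    volume where the mask is False before Doppler processing.
    """
    nx, ny, nz = bmode_db.shape
    grad = np.diff(bmode_db, axis=2)
    iz = np.argmax(grad, axis=2)
    valid = bmode_db.max(axis=2) > gradient_floor_db
    if valid.sum() < 0.3 * nx * ny:
        raise ValueError("skin interface found in fewer than 30% of columns")
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    z_if = grid.z[np.clip(iz + 1, 0, nz - 1)]
    # least-squares 2-D polynomial of total order poly_order
    terms = [(i, j) for i in range(poly_order + 1) for j in range(poly_order + 1) if i + j <= poly_order]
    A = np.column_stack([(X[valid] ** i) * (Y[valid] ** j) for i, j in terms])
    coef, *_ = np.linalg.lstsq(A, z_if[valid], rcond=None)
    surface = sum(c * X**i * Y**j for c, (i, j) in zip(coef, terms))
    mask = grid.z[None, None, :] >= surface[:, :, None]
    return surface, mask


def svd_clutter_filter(
    series: IQVolumeSeries, spec: ClutterFilterSpec | None = None, mask: np.ndarray | None = None
) -> tuple[IQVolumeSeries, np.ndarray]:
    """SVD clutter filter of the Casorati matrix; returns (filtered, singular values).

    Modes 1..ceil(low_fraction * n_slow) (tissue) and the last ``high_count``
    modes (noise) are zeroed; the reconstruction and the full singular-value
    spectrum (for diagnostics) are returned. The filter is a projection:
    applying it twice changes nothing.
    """
    spec = spec or ClutterFilterSpec()
    n_slow = series.n_slow
    lo, hi = spec.mode_range(n_slow)
    if hi <= lo:
        raise ValueError(
            f"ensemble too short: need n_slow > {spec.high_count} + ceil({spec.low_fraction}*n_slow), got {n_slow}"
        )
    cas = series.casorati()
    if mask is not None:
        cas = cas * mask.reshape(-1, 1)
    u, s, vh = np.linalg.svd(cas, full_matrices=False)
    filt = (u[:, lo:hi] * s[lo:hi]) @ vh[lo:hi]
    out = IQVolumeSeries(
        filt.reshape(series.data.shape), series.grid, series.framerate_hz, series.f0, series.provenance
    )
    return out, s


def power_doppler(filtered: IQVolumeSeries) -> np.ndarray:
    """Mean slow-time power per voxel of the clutter-filtered series."""
    return np.mean(np.abs(filtered.data) ** 2, axis=-1)


def signed_power_doppler(filtered: IQVolumeSeries) -> np.ndarray:
    """Power Doppler signed by flow direction (toward the array positive).

    The sign is the sign of the mean Doppler frequency, read from the phase
    of the lag-1 slow-time autocorrelation. Motion toward the array shortens
    the round trip, advancing the slow-time phase.
    """
    d = filtered.data
    r1 = np.sum(d[..., 1:] * np.conj(d[..., :-1]), axis=-1)
    sign = np.sign(np.angle(r1))
    sign[sign == 0] = 1.0
    return sign * power_doppler(filtered)


def spectral_doppler(
    filtered: IQVolumeSeries,
    roi_center: tuple[int, int, int],
    roi: int = 3,
    window: int = 30,
    c: float = 1480.0,
) -> SpectralDoppler:
    """ROI-averaged short-time Fourier spectrogram mapped to axial velocity.

    A Hann-windowed ``window``-point STFT (50% overlap) is computed per voxel
    of the ``roi``^3 neighborhood and the magnitudes are averaged. Doppler
    frequency maps to axial velocity via v = c * f_d / (2 f0); velocities
    beyond c * framerate / (4 f0) alias.
    """
    h = roi // 2
    c0 = np.asarray(roi_center)
    shape = filtered.data.shape[:3]
    if np.any(c0 - h < 0) or np.any(c0 + h >= shape):
        raise ValueError("ROI outside the volume grid")
    sl = tuple(slice(c - h, c + h + 1) for c in c0)
    sig = filtered.data[sl].reshape(-1, filtered.n_slow)

    fr = filtered.framerate_hz
    stft = ShortTimeFFT(hann(window, sym=False), hop=window // 2, fs=fr, fft_mode="centered")
    mags = np.abs(stft.stft(sig, axis=-1))  # (n_roi, n_freq, n_times)
    mag = mags.mean(axis=0)
    freqs = stft.f
    # scipy's hop-based time axis; keep entries covering the signal
    times = stft.t(filtered.n_slow)
    velocity = freqs * c / (2.0 * filtered.f0)
    return SpectralDoppler(mag, velocity, times, window)


def resistive_index(mean_velocity_waveform: np.ndarray, framerate_hz: float | None = None, min_cycle_s: float = 0.4) -> float:
    """Resistive index of a velocity-envelope waveform, averaged over cycles.

    Per cardiac cycle (peak-to-peak interval between systolic maxima):
    RI = (peak systolic - end diastolic) / peak systolic. Constant flow
    gives 0.
    """
    v = np.asarray(mean_velocity_waveform, float)
    if v.size < 3:
        raise ValueError("waveform too short")
    if v.max() <= 0:
        raise ValueError("non-positive peak velocity")
    distance = max(1, int(min_cycle_s * framerate_hz)) if framerate_hz else max(1, v.size // 20)
    prom = 0.25 * (v.max() - v.min())
    if prom == 0:  # constant flow
        return 0.0
    peaks, _ = find_peaks(v, distance=distance, prominence=prom)
    if len(peaks) < 2:
        # single cycle visible: fall back to global extrema
        return float((v.max() - v.min()) / v.max())
    ris = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        psv = v[a]
        edv = v[a:b].min()
        if psv > 0:
            ris.append((psv - edv) / psv)
    if not ris:
        raise ValueError("no valid cardiac cycles found")
    return float(np.mean(ris))
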