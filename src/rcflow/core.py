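"""Shared domain containers for the row-column-array (RCA) imaging chain.

Geometry conventions used throughout the package:

* ``x`` is the position axis of the *column* elements, ``y`` the position axis
  of the *row* elements, ``z`` is depth into the medium from the array plane.
  The origin sits at the array center.
* A "rows" transmit uses the row elements (positions along ``y``, strips
  extended along ``x``); reception then happens on the column elements
  (positions along ``x``) and vice versa.
* Strip elements are delay-invariant along their long axis: all receive
  distances are computed in the plane orthogonal to that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArraySpec", "PulseSpec", "Medium", "VoxelGrid"]


@dataclass(frozen=True)
class ArraySpec:
    """Row-column array geometry.

    The reference design is 64 rows + 64 columns at 150-um pitch, i.e. a
    9.6 mm x 9.6 mm aperture addressed by 128 channels.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch: float = 150e-6
    element_width: float = 150e-6

    def __post_init__(self) -> None:
        if self.n_rows != self.n_cols:
            raise ValueError("RCA design requires n_rows == n_cols")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.element_width > self.pitch:
            raise ValueError("element_width cannot exceed pitch")

    @property
    def aperture(self) -> float:
        """Aperture extent along either axis (n * pitch), in meters."""
        return self.n_cols * self.pitch

    def element_positions(self) -> np.ndarray:
        """Element center coordinates along the addressing axis, centered on 0."""
        n = self.n_cols
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch


@dataclass(frozen=True)
class PulseSpec:
    """Transmit excitation and transducer band limit.

    The excitation is a Hann-windowed sinusoid burst; ``bandwidth_frac`` is
    the one-way fractional -6 dB bandwidth of the transducer, applied twice
    (transmit and receive) as a Gaussian-envelope impulse response when
    synthesizing echoes. Defaults follow the characterized array (9.02 MHz
    center frequency, 73% bandwidth, 2 cycles, 100 MHz sampling); set
    ``bandwidth_frac=None`` for an ideal wideband transducer.
    """

    f0: float = 9.02e6
    n_cycles: int = 2
    fs: float = 100e6
    envelope: str = "hann"
    bandwidth_frac: float | None = 0.73

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.f0:
            raise ValueError("fs must exceed 2*f0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.envelope != "hann":
            raise ValueError("only the 'hann' envelope is supported")
        if self.bandwidth_frac is not None and not 0 < self.bandwidth_frac < 2:
            raise ValueError("bandwidth_frac must be in (0, 2)")

    @property
    def duration(self) -> float:
        """Excitation burst duration (s)."""
        return self.n_cycles / self.f0

    def excitation(self, oversample: int = 1) -> np.ndarray:
        """Sampled Hann-windowed burst at ``oversample * fs``."""
        fs = self.fs * oversample
        n = int(np.ceil(self.duration * fs)) + 1
        t = np.arange(n) / fs
        w = np.sin(2 * np.pi * self.f0 * t) * 0.5 * (1 - np.cos(2 * np.pi * t / self.duration))
        w[t > self.duration] = 0.0
        return w

    def impulse_response(self, oversample: int = 1) -> np.ndarray:
        """One-way transducer impulse response (Gaussian envelope at f0)."""
        if self.bandwidth_frac is None:
            return np.array([1.0])
        fs = self.fs * oversample
        sigma_f = self.bandwidth_frac * self.f0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        half = int(np.ceil(3.5 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        h = np.exp(-(t**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * self.f0 * t)
        return h / np.abs(h).sum() * 2.0  # keep the convolution near unit gain

    def two_way_pulse(self, oversample: int = 8) -> tuple[np.ndarray, float, float]:
        """Effective received waveform: excitation through tx and rx band limits.

        Returns ``(samples, fs_pulse, t_peak)`` where ``t_peak`` is the
        envelope-peak lag used by the beamformer.
        """
        fs = self.fs * oversample
        p = self.excitation(oversample)
        h = self.impulse_response(oversample)
        eff = np.convolve(np.convolve(p, h), h)
        eff = eff / np.abs(eff).max()
        from scipy.signal import hilbert  # local import keeps core scipy-light

        t_peak = float(np.argmax(np.abs(hilbert(eff)))) / fs
        return eff, fs, t_peak


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium (water-like tissue mimic by default)."""

    c: float = 1480.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("sound speed must be positive")

    def wavelength(self, f0: float) -> float:
        return self.c / f0


@dataclass(frozen=True)
class VoxelGrid:
    """Rectilinear voxel grid; coordinate vectors are voxel centers in meters."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or v.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-D vector")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if np.any(self.z < 0):
            raise ValueError("z (depth) must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def spacing(self) -> tuple[float, float, float]:
        def step(v: np.ndarray) -> float:
            return float(v[1] - v[0]) if v.size > 1 else 0.0

        return (step(self.x), step(self.y), step(self.z))

    @classmethod
    def regular(
        cls,
        x_span: tuple[float, float],
        y_span: tuple[float, float],
        z_span: tuple[float, float],
        spacing: tuple[float, float, float],
    ) -> "VoxelGrid":
        """Build a grid from inclusive spans and per-axis spacings."""
        axes = []
        for (lo, hi), d in zip((x_span, y_span, z_span), spacing):
            n = int(round((hi - lo) / d)) + 1
            axes.append(lo + d * np.arange(n))
        return cls(*axes)
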