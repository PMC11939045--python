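"""Transmit-scheme definitions for the RCA sensor.

Four schemes are supported:

* ``SA``   -- single-element synthetic aperture: each of the 64 elements of one
  array transmits sequentially (64 events, 1 active element each).
* ``HSA``  -- Hadamard-encoded synthetic aperture: all 64 elements fire on every
  event with +-1 polarities taken from the rows of a Sylvester Hadamard matrix;
  a linear decode re-forms the SA data with an SNR gain of sqrt(order).
* ``SPW``  -- single-array plane waves: one array steers plane waves over a
  symmetric angle fan; the orthogonal array receives.
* ``OPW``  -- orthogonal plane waves: the SPW fan emitted first on the rows
  array then on the columns array; the two orientations are later compounded
  coherently for a symmetric PSF.

The compound frame rate of a scheme is ``prf / n_events``; e.g. 64 transmits at
a 20 kHz PRF give 312.5 volumes/s, and 400 such frames span 1.28 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard as _sylvester_hadamard

from .core import ArraySpec

__all__ = [
    "TransmitEvent",
    "TransmitScheme",
    "hadamard_matrix",
    "build_scheme",
    "plane_wave_delays",
    "frame_rate",
    "hadamard_encode",
    "hadamard_decode",
]

#: Angle fans (degrees) used when a plane-wave scheme does not specify a span:
#: symmetric 1-degree grids centered on broadside, continuing the printed
#: pattern of the reference sequences (32 angles: -15.5..15.5, 16: -7.5..7.5).
DEFAULT_ANGLE_STEP_DEG = 1.0

#: Angle step (deg) beyond which transmit grating artifacts from the angular
#: sampling itself become a concern; larger steps trigger a warning.
MAX_SAFE_ANGLE_STEP_DEG = 2.0


@dataclass(frozen=True)
class TransmitEvent:
    """One emission: transmitting axis, per-element polarity, steering angle."""

    tx_axis: str  # "rows" | "cols"
    polarities: np.ndarray  # (n_elements,), entries in {-1, 0, +1}
    steer_angle_deg: float = 0.0
    event_index: int = 0

    def __post_init__(self) -> None:
        if self.tx_axis not in ("rows", "cols"):
            raise ValueError("tx_axis must be 'rows' or 'cols'")
        pol = np.asarray(self.polarities, dtype=np.int8)
        object.__setattr__(self, "polarities", pol)
        if not np.isin(pol, (-1, 0, 1)).all():
            raise ValueError("polarities must be in {-1, 0, +1}")

    @property
    def rx_axis(self) -> str:
        return "cols" if self.tx_axis == "rows" else "rows"

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.polarities))


@dataclass(frozen=True)
class TransmitScheme:
    """Ordered emission plan plus repetition timing."""

    name: str  # "SA" | "HSA" | "SPW" | "OPW"
    events: tuple
    prf_hz: float
    angles_deg: tuple = ()

    def __post_init__(self) -> None:
        if self.prf_hz <= 0:
            raise ValueError("prf_hz must be positive")
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "angles_deg", tuple(self.angles_deg))

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def frame_rate_hz(self) -> float:
        return self.prf_hz / self.n_events

    def frame_period(self) -> float:
        return 1.0 / self.frame_rate_hz

    def split_by_axis(self) -> tuple[list[int], list[int]]:
        """Indices of rows-transmitting and cols-transmitting events."""
        rows = [i for i, e in enumerate(self.events) if e.tx_axis == "rows"]
        cols = [i for i, e in enumerate(self.events) if e.tx_axis == "cols"]
        return rows, cols

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "prf_hz": self.prf_hz,
            "n_events": self.n_events,
            "angles_deg": list(self.angles_deg),
            "events": [
                {
                    "tx_axis": e.tx_axis,
                    "polarities": e.polarities.tolist(),
                    "steer_angle_deg": e.steer_angle_deg,
                    "event_index": e.event_index,
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransmitScheme":
        events = [
            TransmitEvent(
                tx_axis=e["tx_axis"],
                polarities=np.asarray(e["polarities"], dtype=np.int8),
                steer_angle_deg=e["steer_angle_deg"],
                event_index=e["event_index"],
            )
            for e in d["events"]
        ]
        return cls(name=d["name"], events=tuple(events), prf_hz=d["prf_hz"], angles_deg=tuple(d["angles_deg"]))


def hadamard_matrix(order: int) -> np.ndarray:
    """Sylvester Hadamard matrix of the given power-of-two order.

    Satisfies ``H @ H.T == order * I`` with an all-ones first row and column.
    """
    if order < 2 or order > 64 or (order & (order - 1)) != 0:
        raise ValueError(f"order must be a power of 2 in [2, 64], got {order}")
    return _sylvester_hadamard(order).astype(np.int8)


def _angle_grid(span_deg: tuple[float, float], step_deg: float) -> np.ndarray:
    lo, hi = span_deg
    n_steps = (hi - lo) / step_deg
    n = int(round(n_steps))
    if abs(n_steps - n) > 1e-9:
        raise ValueError(f"angle span {span_deg} is not an integer number of {step_deg} deg steps")
    return lo + step_deg * np.arange(n + 1)


def build_scheme(
    kind: str,
    array: ArraySpec | None = None,
    prf_hz: float = 20e3,
    angle_span_deg: tuple[float, float] | None = None,
    angle_step_deg: float = DEFAULT_ANGLE_STEP_DEG,
    n_angles: int | None = None,
    tx_axis: str = "rows",
) -> TransmitScheme:
    """Construct one of the four transmit schemes.

    For plane-wave kinds the fan may be given either as an explicit
    ``angle_span_deg`` or as ``n_angles`` (a symmetric 1-degree grid centered
    on broadside, e.g. 32 -> -15.5..15.5, 16 -> -7.5..7.5). OPW emits the fan
    on the rows array first, then on the columns array, all angles ascending.
    """
    array = array or ArraySpec()
    n = array.n_cols
    kind = kind.upper()

    if kind in ("SA", "HSA"):
        if kind == "SA":
            events = []
            for m in range(n):
                pol = np.zeros(n, dtype=np.int8)
                pol[m] = 1
                events.append(TransmitEvent(tx_axis, pol, 0.0, m))
        else:
            H = hadamard_matrix(n)
            events = [TransmitEvent(tx_axis, H[m], 0.0, m) for m in range(n)]
        return TransmitScheme(kind, tuple(events), prf_hz)

    if kind not in ("SPW", "OPW"):
        raise ValueError(f"unknown scheme kind {kind!r}")

    if angle_span_deg is None:
        if n_angles is None:
            raise ValueError("plane-wave schemes need angle_span_deg or n_angles")
        half = (n_angles - 1) / 2.0 * angle_step_deg
        angle_span_deg = (-half, half)
    angles = _angle_grid(angle_span_deg, angle_step_deg)
    if angle_step_deg > MAX_SAFE_ANGLE_STEP_DEG:
        warnings.warn(
            f"angle step {angle_step_deg} deg exceeds the grating-safe maximum "
            f"{MAX_SAFE_ANGLE_STEP_DEG} deg",
            stacklevel=2,
        )

    all_pos = np.ones(n, dtype=np.int8)
    events: list[TransmitEvent] = []
    axes = ("rows", "cols") if kind == "OPW" else (tx_axis,)
    idx = 0
    for ax in axes:
        for a in angles:
            events.append(TransmitEvent(ax, all_pos, float(a), idx))
            idx += 1
    return TransmitScheme(kind, tuple(events), prf_hz, tuple(float(a) for a in angles))


def plane_wave_delays(angle_deg: float, element_positions: np.ndarray, c: float) -> np.ndarray:
    """Per-element firing delays (s) of a linear steered plane wave.

    Delays are linear in element position and min-shifted so the first element
    fires at t = 0; their span is ``aperture * |sin(angle)| / c``.
    """
    if c <= 0:
        raise ValueError("sound speed must be positive")
    pos = np.asarray(element_positions, dtype=float)
    d = pos * np.sin(np.deg2rad(angle_deg)) / c
    return d - d.min()


def frame_rate(scheme: TransmitScheme) -> float:
    """Compound volume rate in Hz: PRF divided by transmits per frame."""
    return scheme.frame_rate_hz


def hadamard_encode(sa_events: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Combine per-element (SA) event data into Hadamard-encoded events.

    ``sa_events`` has the event axis first; encoded event m is
    ``sum_k H[m, k] * sa_events[k]``.
    """
    sa = np.asarray(sa_events)
    if sa.shape[0] != H.shape[0]:
        raise ValueError("event count must equal the Hadamard order")
    return np.tensordot(H.astype(sa.dtype if sa.dtype.kind == "f" else float), sa, axes=(1, 0))


def hadamard_decode(encoded_events: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Invert Hadamard encoding; exact left inverse of :func:`hadamard_encode`.

    Decoded event k is ``(1/order) * sum_m H[m, k] * encoded[m]``, so in a
    noiseless linear acquisition the result equals the SA data while iid noise
    variance drops by 1/order (amplitude SNR gain sqrt(order)).
    """
    enc = np.asarray(encoded_events)
    order = H.shape[0]
    if enc.shape[0] != order:
        raise ValueError(f"expected {order} encoded events, got {enc.shape[0]}")
    return np.tensordot(H.T.astype(float) / order, enc, axes=(1, 0))
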