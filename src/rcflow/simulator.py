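"""Linear time-of-flight RF synthesis for RCA transmit schemes.

The model is a far-field superposition of point-scatterer echoes: each
scatterer returns a delayed copy of the transmit burst with an amplitude set
by its reflectivity and the strip-element directivities of the transmit and
receive legs. Plane-wave transmits use the steered-wavefront arrival time
(min-shifted delay law); synthetic-aperture transmits use a cylindrical wave
from the active strip, with all distances computed in the plane orthogonal to
the strip's long axis. No attenuation, no 1/r spreading (all downstream
metrics are relative), no nonlinearity.

Axial scatterer motion between compound frames produces the expected
slow-time Doppler phase of 4*pi*f0*v / (c * framerate) per frame as an
emergent property of the geometry; nothing is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .core import ArraySpec, Medium, PulseSpec
from .phantoms import Phantom, advance_phantom
from .sequences import TransmitScheme, hadamard_matrix, hadamard_decode

__all__ = [
    "ChannelData",
    "pulse_waveform",
    "element_directivity",
    "simulate_ensemble",
    "add_noise",
    "decode_hsa",
]


@dataclass(frozen=True)
class ChannelData:
    """Per-event, per-receive-channel echoes over slow time.

    ``samples`` is ``[frame, event, receive_channel, time_sample]``; real RF
    as simulated, complex after baseband demodulation (``is_baseband``).
    """

    samples: np.ndarray
    fs: float
    prf_hz: float
    scheme: TransmitScheme
    array: ArraySpec
    pulse: PulseSpec
    medium: Medium
    is_baseband: bool = False
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.samples.ndim != 4:
            raise ValueError("samples must be [frame, event, channel, time]")
        if self.samples.shape[1] != self.scheme.n_events:
            raise ValueError("event axis does not match the scheme")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def frame_rate_hz(self) -> float:
        return self.prf_hz / self.scheme.n_events


def pulse_waveform(spec: PulseSpec) -> np.ndarray:
    """Sampled transmit burst: Hann-windowed sinusoid of n_cycles/f0 duration."""
    return spec.excitation()


def element_directivity(angle: np.ndarray, width: float, wavelength: float) -> np.ndarray:
    """Far-field strip-element gain |sinc(w sin(a)/lambda)| cos(a), 1 at broadside."""
    angle = np.asarray(angle, float)
    if np.any(np.abs(angle) >= np.pi / 2):
        raise ValueError("|angle| must be < pi/2")
    return np.abs(np.sinc(width * np.sin(angle) / wavelength)) * np.cos(angle)


def _event_geometry(event, array: ArraySpec):
    """(u, w) picker: u = tx-position axis, w = rx-position axis.

    Rows transmit -> u is the y coordinate, w is x; columns transmit swaps.
    """
    if event.tx_axis == "rows":
        return 1, 0  # u <- y, w <- x
    return 0, 1


def simulate_ensemble(
    phantom: Phantom,
    scheme: TransmitScheme,
    pulse: PulseSpec | None = None,
    medium: Medium | None = None,
    array: ArraySpec | None = None,
    n_frames: int = 1,
    depth_max: float = 8e-3,
    use_directivity: bool = True,
    frames: "np.ndarray | None" = None,
) -> ChannelData:
    """Synthesize RF channel data for a phantom under a transmit scheme.

    Scatterers are frozen within each compound frame and advanced to slow
    time ``i * n_events / prf`` between frames. ``frames`` may select a
    subset of frame indices (for streaming pipelines).
    """
    pulse = pulse or PulseSpec()
    medium = medium or Medium()
    array = array or ArraySpec()
    if any(e.polarities.shape[0] != array.n_cols for e in scheme.events):
        raise ValueError("scheme polarities do not match the array element count")
    if np.any(phantom.positions[:, 2] > depth_max):
        raise ValueError("scatterers beyond depth_max are outside the recorded window")

    elem_pos = array.element_positions()
    wavelength = medium.wavelength(pulse.f0)
    eff_pulse, fs_pulse, _ = pulse.two_way_pulse()
    pulse_T = (eff_pulse.size - 1) / fs_pulse
    n_t = int(np.ceil((2 * depth_max / medium.c + pulse_T) * pulse.fs)) + 4
    frame_idx = np.arange(n_frames) if frames is None else np.asarray(frames)
    out = np.zeros((len(frame_idx), scheme.n_events, array.n_cols, n_t))
    frame_period = scheme.n_events / scheme.prf_hz

    empty = np.zeros(0)
    for fi, frame in enumerate(frame_idx):
        ph = advance_phantom(phantom, float(frame) * frame_period)
        pos = ph.positions
        amp = ph.amplitudes
        for ei, event in enumerate(scheme.events):
            iu, iw = _event_geometry(event, array)
            if scheme.name in ("SPW", "OPW"):
                a = np.deg2rad(event.steer_angle_deg)
                sin_a, cos_a = np.sin(a), np.cos(a)
                t0_pw = -np.min(elem_pos * sin_a) / medium.c
                _kernels.simulate_event(
                    out[fi, ei],
                    _kernels.TX_PLANE_WAVE,
                    sin_a,
                    cos_a,
                    t0_pw,
                    empty,
                    empty,
                    elem_pos,
                    pos[:, iu].copy(),
                    pos[:, iw].copy(),
                    pos[:, 2].copy(),
                    amp,
                    medium.c,
                    pulse.fs,
                    eff_pulse,
                    fs_pulse,
                    array.element_width / wavelength,
                    use_directivity,
                )
            else:
                _kernels.simulate_event(
                    out[fi, ei],
                    _kernels.TX_ELEMENTS,
                    0.0,
                    1.0,
                    0.0,
                    elem_pos,
                    event.polarities.astype(np.float64),
                    elem_pos,
                    pos[:, iu].copy(),
                    pos[:, iw].copy(),
                    pos[:, 2].copy(),
                    amp,
                    medium.c,
                    pulse.fs,
                    eff_pulse,
                    fs_pulse,
                    array.element_width / wavelength,
                    use_directivity,
                )
    return ChannelData(out, pulse.fs, scheme.prf_hz, scheme, array, pulse, medium)


def decode_hsa(data: ChannelData) -> ChannelData:
    """Hadamard-decode an HSA acquisition back to per-element (SA) events."""
    if data.scheme.name != "HSA":
        raise ValueError("decode_hsa expects an HSA acquisition")
    H = hadamard_matrix(data.array.n_cols)
    dec = np.empty_like(data.samples, dtype=float if not data.is_baseband else complex)
    for f in range(data.n_frames):
        dec[f] = hadamard_decode(data.samples[f], H)
    # decoded event k is the single-element transmit of element k
    from .sequences import build_scheme

    sa = build_scheme("SA", data.array, data.scheme.prf_hz, tx_axis=data.scheme.events[0].tx_axis)
    return replace(data, samples=dec, scheme=sa)


def add_noise(data: ChannelData, snr_db: float | None, seed: int = 0) -> ChannelData:
    """Add iid Gaussian noise at the requested SNR over nonzero-signal samples.

    ``snr_db=None`` (infinite SNR) returns the input unchanged.
    """
    if snr_db is None or np.isinf(snr_db):
        return data
    s = data.samples
    nz = s != 0
    if not np.any(nz):
        raise ValueError("cannot scale noise against all-zero data")
    p_sig = np.mean(np.abs(s[nz]) ** 2)
    p_noise = p_sig / 10 ** (snr_db / 10)
    rng = np.random.default_rng(seed)
    if np.iscomplexobj(s):
        noise = rng.normal(0, np.sqrt(p_noise / 2), s.shape) + 1j * rng.normal(0, np.sqrt(p_noise / 2), s.shape)
    else:
        noise = rng.normal(0, np.sqrt(p_noise), s.shape)
    return replace(data, samples=s + noise)
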