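"""3-D delay-and-sum beamforming for the RCA geometry.

Each transmit event focuses one lateral axis (synthetically, through the
plane-wave fan or the synthetic aperture) while the orthogonal receive array
focuses the other, so a single event already yields a full 3-D volume.
Coherent compounding over events sharpens both axes; for orthogonal plane
waves the rows-transmit and columns-transmit halves are averaged coherently,
which symmetrizes the PSF. XDoppler replaces that coherent sum by a slow-time
correlation of the two orientations, which cancels incoherent noise.

Baseband convention: after IQ demodulation at ``f0`` the analytic sample at
delay ``tau`` is reconstructed as ``bb(tau) * exp(+2j*pi*f0*tau)``. The
plane-wave delay law is min-shifted (first element fires at t = 0), matching
the simulator bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve, firwin

from . import _kernels
from .core import ArraySpec, Medium, PulseSpec, VoxelGrid
from .simulator import ChannelData

__all__ = [
    "IQVolumeSeries",
    "demodulate",
    "das_rca",
    "beamform_series",
    "xdoppler_power",
    "bmode",
]


@dataclass(frozen=True)
class IQVolumeSeries:
    """Beamformed complex volumes on a voxel grid over slow time."""

    data: np.ndarray  # (nx, ny, nz, n_slow) complex
    grid: VoxelGrid
    framerate_hz: float
    f0: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be (nx, ny, nz, n_slow)")

    @property
    def n_slow(self) -> int:
        return self.data.shape[3]

    def casorati(self) -> np.ndarray:
        """(n_voxels, n_slow) view of the series."""
        return self.data.reshape(-1, self.n_slow)


def demodulate(data: ChannelData, f0: float | None = None, n_taps: int = 101, rel_cutoff: float = 0.8) -> ChannelData:
    """IQ-demodulate real RF: mix at f0, low-pass at the pulse bandwidth.

    The complex output is scaled so that ``|bb|`` matches the RF envelope.
    """
    if data.is_baseband:
        raise ValueError("data is already baseband")
    f0 = f0 or data.pulse.f0
    n_t = data.samples.shape[-1]
    t = np.arange(n_t) / data.fs
    mixed = data.samples * np.exp(-2j * np.pi * f0 * t)
    taps = firwin(n_taps, rel_cutoff * f0, fs=data.fs)
    bb = 2.0 * fftconvolve(mixed, taps[None, None, None, :], mode="same", axes=-1)
    return replace(data, samples=bb, is_baseband=True)


def _rx_tables(grid_w, z, rx_pos, c, f0, rx_fnumber, apodization):
    """Receive delay and apodized phase tables for one receive axis.

    Returns (tau_rx (n_rx, nw, nz), apod*exp(i*2*pi*f0*tau_rx))."""
    w = grid_w[None, :, None]
    zz = z[None, None, :]
    dj = rx_pos[:, None, None]
    tau = np.sqrt((w - dj) ** 2 + zz**2) / c
    if rx_fnumber and rx_fnumber > 0:
        half = zz / (2.0 * rx_fnumber)
        u = (dj - w) / half
        if apodization == "hann":
            apod = np.where(np.abs(u) < 1.0, 0.5 + 0.5 * np.cos(np.pi * u), 0.0)
        elif apodization == "rect":
            apod = (np.abs(u) < 1.0).astype(float)
        else:
            raise ValueError(f"unknown apodization {apodization!r}")
    else:  # f-number 0: full aperture, uniform
        apod = np.ones_like(tau)
    norm = apod.sum(axis=0, keepdims=True)
    norm[norm == 0] = 1.0
    apod = apod / norm
    return tau, (apod * np.exp(2j * np.pi * f0 * tau)).astype(np.complex128)


def _tx_tables(event, grid_u, z, elem_pos, c, f0, tx_fnumber=0.5):
    """Transmit delay table over (u, z), its weighted phase rotator, and weight.

    Single-element (synthetic aperture) transmits get a dynamic Hann
    apodization over the synthetic transmit aperture (half-width
    ``z / (2 * tx_fnumber)`` centered on the voxel), the transmit-side mirror
    of the receive taper; plane waves are unweighted.
    """
    if event.n_active == 1:
        m = int(np.flatnonzero(event.polarities)[0])
        du = grid_u[:, None] - elem_pos[m]
        tau = np.sqrt(du**2 + z[None, :] ** 2) / c
        if tx_fnumber and tx_fnumber > 0:
            u_rel = du / (z[None, :] / (2.0 * tx_fnumber))
            wt = np.where(np.abs(u_rel) < 1.0, 0.5 + 0.5 * np.cos(np.pi * u_rel), 0.0)
        else:
            wt = np.ones_like(tau)
    else:
        a = np.deg2rad(event.steer_angle_deg)
        t0 = -np.min(elem_pos * np.sin(a)) / c
        tau = (grid_u[:, None] * np.sin(a) + z[None, :] * np.cos(a)) / c + t0
        wt = np.ones_like(tau)
    return tau, (wt * np.exp(2j * np.pi * f0 * tau)).astype(np.complex128), wt


def das_rca(
    event_bb: np.ndarray,
    event,
    grid: VoxelGrid,
    medium: Medium,
    array: ArraySpec,
    f0: float,
    fs: float,
    rx_fnumber: float = 1.0,
    apodization: str = "hann",
    t_lag: float = 0.0,
) -> np.ndarray:
    """Delay-and-sum one event's baseband channels onto the voxel grid.

    ``event_bb`` is (n_rx, n_t) complex baseband. ``t_lag`` shifts the
    envelope sampling time (use half the pulse duration so the image peaks
    at the geometric scatterer depth). Returns an (nx, ny, nz) complex
    volume. Voxels whose delays fall outside the recorded window contribute
    zero.
    """
    if not np.iscomplexobj(event_bb):
        raise ValueError("das_rca expects complex baseband channel data")
    elem_pos = array.element_positions()
    z = grid.z
    if event.tx_axis == "rows":
        grid_u, grid_w = grid.y, grid.x
    else:
        grid_u, grid_w = grid.x, grid.y
    tau_rx, ph_rx = _rx_tables(grid_w, z, elem_pos, medium.c, f0, rx_fnumber, apodization)
    tau_tx, ph_tx, _ = _tx_tables(event, grid_u, z, elem_pos, medium.c, f0)
    out = np.zeros((grid_u.size, grid_w.size, z.size), dtype=np.complex128)
    _kernels.das_event(np.ascontiguousarray(event_bb, np.complex128), tau_tx, ph_tx, tau_rx, ph_rx, fs, t_lag, out)
    if event.tx_axis == "rows":  # (u=y, w=x, z) -> (x, y, z)
        out = out.transpose(1, 0, 2)
    return out


def beamform_series(
    data: ChannelData,
    grid: VoxelGrid,
    rx_fnumber: float = 1.0,
    apodization: str = "hann",
    tx_fnumber: float = 0.5,
    split_axes: bool = False,
):
    """Beamform every frame: per-event DAS then coherent mean over events.

    Synthetic-aperture transmits are compounded with a dynamic Hann transmit
    apodization (``tx_fnumber``, default 0.5 = full aperture at mid-FOV) and
    the per-voxel transmit weight is normalized out. With ``split_axes=True``
    (meaningful for OPW), returns the rows-transmit and columns-transmit
    half-series separately (for XDoppler) instead of their coherent mean.
    HSA channel data must be Hadamard-decoded first.
    """
    if data.scheme.name == "HSA":
        raise ValueError("HSA channel data must be decoded (decode_hsa) before beamforming")
    if not data.is_baseband:
        data = demodulate(data)
    f0 = data.pulse.f0
    scheme = data.scheme
    elem_pos = data.array.element_positions()
    c = data.medium.c

    # receive tables depend only on the receive axis; cache both orientations
    rx_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def rx_tables_for(event):
        gw = grid.x if event.tx_axis == "rows" else grid.y
        key = event.tx_axis
        if key not in rx_cache:
            rx_cache[key] = _rx_tables(gw, grid.z, elem_pos, c, f0, rx_fnumber, apodization)
        return rx_cache[key]

    t_lag = data.pulse.two_way_pulse()[2]  # envelope-peak lag of the effective pulse
    rows_idx, cols_idx = scheme.split_by_axis()
    groups = [rows_idx, cols_idx] if split_axes else [list(range(scheme.n_events))]
    if split_axes and (not rows_idx or not cols_idx):
        raise ValueError("split_axes requires events on both axes (OPW)")

    n_frames = data.n_frames
    shape = grid.shape
    outputs = [np.zeros(shape + (n_frames,), dtype=np.complex128) for _ in groups]
    for fi in range(n_frames):
        for gi, idx in enumerate(groups):
            acc = np.zeros(shape, dtype=np.complex128)
            wsum = np.zeros(shape)
            for ei in idx:
                event = scheme.events[ei]
                grid_u = grid.y if event.tx_axis == "rows" else grid.x
                tau_rx, ph_rx = rx_tables_for(event)
                tau_tx, ph_tx, wt = _tx_tables(event, grid_u, grid.z, elem_pos, c, f0, tx_fnumber)
                vol = np.zeros((grid_u.size, tau_rx.shape[1], grid.z.size), dtype=np.complex128)
                _kernels.das_event(
                    np.ascontiguousarray(data.samples[fi, ei], np.complex128),
                    tau_tx,
                    ph_tx,
                    tau_rx,
                    ph_rx,
                    data.fs,
                    t_lag,
                    vol,
                )
                if event.tx_axis == "rows":  # (u=y, w=x, z) -> (x, y, z)
                    vol = vol.transpose(1, 0, 2)
                    acc += vol
                    wsum += wt[None, :, :]
                else:
                    acc += vol
                    wsum += wt[:, None, :]
            wsum[wsum == 0] = 1.0
            outputs[gi][..., fi] = acc / wsum

    framerate = data.frame_rate_hz
    series = [
        IQVolumeSeries(o, grid, framerate, f0, provenance=f"{scheme.name}{'-' + tag if split_axes else ''}")
        for o, tag in zip(outputs, ["rows-tx", "cols-tx"] if split_axes else [""])
    ]
    return tuple(series) if split_axes else series[0]


def xdoppler_power(series_rt: IQVolumeSeries, series_ct: IQVolumeSeries) -> np.ndarray:
    """Cross-orientation Doppler power: |mean_t V_rt * conj(V_ct)| per voxel.

    Incoherent noise between the two orientations averages out over slow
    time, so the Doppler SNR exceeds that of the coherent-sum power Doppler.
    """
    if series_rt.data.shape != series_ct.data.shape:
        raise ValueError("series length/shape mismatch")
    n = series_rt.n_slow
    return np.abs(np.sum(series_rt.data * np.conj(series_ct.data), axis=-1)) / n


def bmode(volume: np.ndarray) -> np.ndarray:
    """Log-compressed envelope: 20 log10(|v| / max |v|), peak at 0 dB."""
    mag = np.abs(volume)
    peak = mag.max()
    if peak == 0:
        raise ValueError("all-zero volume")
    with np.errstate(divide="ignore"):
        return 20 * np.log10(mag / peak)
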