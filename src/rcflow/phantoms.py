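"""Digital phantoms and physiological ground-truth generators.

The generators emulate the bench and in vivo conditions the processing chain
is designed for:

* a point target (metal bead) for PSF studies,
* a 500-um flow channel in gel with 1 cm/s blood-mimicking flow,
* a subcutaneous vascular plexus (300-800 um vessels ~1 mm deep) fed by a
  ~1-mm artery at ~4 mm depth, with pulsatile flow at a target resistive
  index,
* an ECG R-peak train with heart-rate variability,
* the 30 s baseline / 30 s cold / 60 s hot peripheral-blood-volume protocol
  sampled at 0.5 Hz.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "LABEL_GEL",
    "LABEL_BLOOD",
    "LABEL_BEAD",
    "FlowSegment",
    "PulsatileWaveform",
    "Phantom",
    "StimulusProtocol",
    "ECGTrace",
    "make_bead_phantom",
    "make_flow_tube",
    "make_vascular_tree",
    "advance_phantom",
    "make_ecg_trace",
    "make_stimulus_pbv",
    "hrf_kernel_params_from_timing",
]

LABEL_GEL = 0
LABEL_BLOOD = 1
LABEL_BEAD = 2


@dataclass(frozen=True)
class PulsatileWaveform:
    """Periodic systole/diastole velocity shape ``w(t)`` with mean 1.

    A raised-cosine (sin^2) systolic bump over the first ``systole_fraction``
    of the cycle decays exponentially into a flat diastole. The diastolic
    floor is chosen so that ``(max w - min w) / max w`` equals the target
    resistive index.
    """

    period_s: float = 0.86
    resistive_index: float = 0.57
    systole_fraction: float = 0.30
    tail_amplitude: float = 0.25
    tail_tau_fraction: float = 0.12
    _n_lut: int = 2048

    def _shape(self, phase: np.ndarray) -> np.ndarray:
        """Unit-peak systolic shape h(phase), phase in [0, 1)."""
        h = np.zeros_like(phase)
        fs = self.systole_fraction
        sys = phase < fs
        h[sys] = np.sin(np.pi * phase[sys] / fs) ** 2
        dia = ~sys
        h[dia] = self.tail_amplitude * np.exp(-(phase[dia] - fs) / self.tail_tau_fraction)
        return h

    def _lut(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        phase = np.arange(self._n_lut) / self._n_lut
        h = self._shape(phase)
        h_min = h.min()
        if self.resistive_index >= 1.0 - 1e-9:
            raise ValueError("resistive_index must be < 1")
        floor = 1.0 - self.resistive_index / (1.0 - h_min)
        if floor < 0:
            raise ValueError("resistive_index too large for this waveform shape")
        w = floor + (1.0 - floor) * h
        w = w / w.mean()
        cum = np.concatenate(([0.0], np.cumsum(w))) * (self.period_s / self._n_lut)
        return phase, w, cum

    def value(self, t: np.ndarray) -> np.ndarray:
        """w(t): normalized velocity multiplier (time-average 1)."""
        phase_lut, w, _ = self._lut()
        ph = np.mod(np.asarray(t, dtype=float), self.period_s) / self.period_s
        return np.interp(ph, np.concatenate((phase_lut, [1.0])), np.concatenate((w, [w[0]])))

    def displacement(self, t: np.ndarray) -> np.ndarray:
        """Integral of w from 0 to t (units of seconds; multiply by v_mean)."""
        _, w, cum = self._lut()
        t = np.asarray(t, dtype=float)
        n_per = np.floor(t / self.period_s)
        frac = t - n_per * self.period_s
        idx = frac / self.period_s * self._n_lut
        within = np.interp(idx, np.arange(self._n_lut + 1), cum)
        return n_per * self.period_s + within  # mean(w) == 1 over a period

    def measured_ri(self) -> float:
        _, w, _ = self._lut()
        return float((w.max() - w.min()) / w.max())


@dataclass(frozen=True)
class FlowSegment:
    """Straight cylindrical vessel segment with axial flow and inlet recycling."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    speed: float  # time-average axial speed, m/s (signed along p0->p1)
    waveform: PulsatileWaveform | None = None

    @property
    def axis(self) -> np.ndarray:
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.p1, float) - np.asarray(self.p0, float)))

    def displacement(self, t: float) -> float:
        """Axial displacement (m) of the flow at time t since t=0."""
        if self.waveform is None:
            return self.speed * t
        return self.speed * float(self.waveform.displacement(np.asarray([t]))[0])


@dataclass(frozen=True)
class Phantom:
    """Scatterer cloud with compartment labels and an optional flow model.

    ``positions`` are the time-zero coordinates; use :func:`advance_phantom`
    for slow-time kinematics. Blood scatterers that flow past the end of
    their segment re-enter at its inlet, keeping the density stationary.
    """

    positions: np.ndarray  # (n, 3) at t = 0
    amplitudes: np.ndarray  # (n,)
    labels: np.ndarray  # (n,) int8
    segments: tuple = ()
    segment_index: np.ndarray | None = None  # (n,) int32, -1 = static
    axial_offset: np.ndarray | None = None  # (n,) position along segment axis at t=0
    radial_offset: np.ndarray | None = None  # (n, 3) fixed perpendicular offset
    seed: int = 0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, float))
        object.__setattr__(self, "labels", np.asarray(self.labels, np.int8))
        if np.any(pos[:, 2] < 0):
            raise ValueError("scatterer depth z must be >= 0")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def flow_mask(self, grid) -> np.ndarray:
        """Binary (nx, ny, nz) mask of voxels inside any vessel segment."""
        X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        mask = np.zeros(X.shape, dtype=bool)
        for seg in self.segments:
            p0 = np.asarray(seg.p0, float)
            e = seg.axis
            rel = pts - p0
            s = rel @ e
            perp = rel - s[..., None] * e
            d2 = np.sum(perp**2, axis=-1)
            mask |= (s >= 0) & (s <= seg.length) & (d2 <= seg.radius**2)
        return mask

    def __add__(self, other: "Phantom") -> "Phantom":
        seg_off = len(self.segments)
        si_a = self.segment_index if self.segment_index is not None else np.full(self.n_scatterers, -1, np.int32)
        si_b = other.segment_index if other.segment_index is not None else np.full(other.n_scatterers, -1, np.int32)
        si_b = np.where(si_b >= 0, si_b + seg_off, -1)

        def _aux(p, attr, default_shape):
            v = getattr(p, attr)
            return v if v is not None else np.zeros(default_shape)

        return Phantom(
            positions=np.vstack([self.positions, other.positions]),
            amplitudes=np.concatenate([self.amplitudes, other.amplitudes]),
            labels=np.concatenate([self.labels, other.labels]),
            segments=self.segments + other.segments,
            segment_index=np.concatenate([si_a, si_b]).astype(np.int32),
            axial_offset=np.concatenate(
                [_aux(self, "axial_offset", self.n_scatterers), _aux(other, "axial_offset", other.n_scatterers)]
            ),
            radial_offset=np.vstack(
                [_aux(self, "radial_offset", (self.n_scatterers, 3)), _aux(other, "radial_offset", (other.n_scatterers, 3))]
            ),
            seed=self.seed,
        )


def _lap_phase(index: np.ndarray, lap: np.ndarray) -> np.ndarray:
    """Deterministic pseudo-random angle in [0, 2pi) per (scatterer, lap); 0 for lap 0."""
    h = np.sin(index * 12.9898 + lap * 78.233) * 43758.5453
    return 2 * np.pi * (h - np.floor(h)) * (lap > 0)


def advance_phantom(phantom: Phantom, t: float) -> Phantom:
    """Return the phantom with all scatterers moved to slow time ``t``.

    Static scatterers are unchanged; blood scatterers advance along their
    segment axis by the integrated (possibly pulsatile) flow and wrap at the
    segment end back to its inlet, so per-vessel counts are conserved. A
    re-entering scatterer stands in for a fresh particle from the pump: its
    radial offset is rotated about the vessel axis by a deterministic
    lap-dependent angle, so the speckle pattern does not repeat with the
    transit period.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if not phantom.segments or phantom.segment_index is None:
        return phantom
    pos = phantom.positions.copy()
    for i, seg in enumerate(phantom.segments):
        sel = phantom.segment_index == i
        if not np.any(sel):
            continue
        s_tot = phantom.axial_offset[sel] + seg.displacement(float(t))
        lap = np.floor(s_tot / seg.length)
        s = s_tot - lap * seg.length
        e = seg.axis
        r = phantom.radial_offset[sel]
        ang = _lap_phase(np.flatnonzero(sel).astype(float), lap)
        exr = np.cross(np.broadcast_to(e, r.shape), r)
        r_rot = r * np.cos(ang)[:, None] + exr * np.sin(ang)[:, None]
        pos[sel] = np.asarray(seg.p0, float) + np.outer(s, e) + r_rot
    return replace(phantom, positions=pos)


def make_bead_phantom(depth: float = 4.8e-3, amplitude: float = 1.0) -> Phantom:
    """Single static point target at (0, 0, depth): the PSF bead stand-in.

    The physical 180-um bead is below the system PSF, so a point scatterer is
    an adequate model for resolution work.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    return Phantom(
        positions=np.array([[0.0, 0.0, depth]]),
        amplitudes=np.array([amplitude]),
        labels=np.array([LABEL_BEAD], np.int8),
    )


def _fill_cylinder(rng, seg: FlowSegment, density_per_mm3: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniformly fill a segment; returns (axial s, radial offsets, positions)."""
    vol_mm3 = np.pi * (seg.radius * 1e3) ** 2 * (seg.length * 1e3)
    n = rng.poisson(density_per_mm3 * vol_mm3)
    s = rng.uniform(0, seg.length, n)
    r = seg.radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    e = seg.axis
    # two perpendicular unit vectors
    ref = np.array([0.0, 0.0, 1.0]) if abs(e[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n1 = np.cross(e, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(e, n1)
    radial = np.outer(r * np.cos(phi), n1) + np.outer(r * np.sin(phi), n2)
    pos = np.asarray(seg.p0, float) + np.outer(s, e) + radial
    return s, radial, pos


def _speckle_box(rng, x_span, y_span, z_span, density_per_mm3, exclude_segments=()):
    vol_mm3 = (
        (x_span[1] - x_span[0]) * (y_span[1] - y_span[0]) * (z_span[1] - z_span[0]) * 1e9
    )
    n = rng.poisson(density_per_mm3 * vol_mm3)
    pos = np.column_stack(
        [rng.uniform(lo, hi, n) for lo, hi in (x_span, y_span, z_span)]
    )
    keep = np.ones(n, dtype=bool)
    for seg in exclude_segments:
        p0 = np.asarray(seg.p0, float)
        e = seg.axis
        rel = pos - p0
        s = rel @ e
        d2 = np.sum((rel - s[:, None] * e) ** 2, axis=1)
        keep &= ~((s >= 0) & (s <= seg.length) & (d2 <= seg.radius**2))
    return pos[keep]


def _vessel_phantom(
    segments: tuple,
    blood_density: float,
    gel_density: float,
    seed: int,
    fov_x: tuple[float, float],
    fov_y: tuple[float, float],
    fov_z: tuple[float, float],
    blood_amplitude: float = 1.0,
    gel_amplitude: float = 1.0,
) -> Phantom:
    rng = np.random.default_rng(seed)
    pos_list, amp_list, lab_list = [], [], []
    seg_idx, ax_off, rad_off = [], [], []
    for i, seg in enumerate(segments):
        s, radial, pos = _fill_cylinder(rng, seg, blood_density)
        pos_list.append(pos)
        amp_list.append(blood_amplitude * rng.normal(1.0, 0.3, len(s)).clip(0.1))
        lab_list.append(np.full(len(s), LABEL_BLOOD, np.int8))
        seg_idx.append(np.full(len(s), i, np.int32))
        ax_off.append(s)
        rad_off.append(radial)
    gel = _speckle_box(rng, fov_x, fov_y, fov_z, gel_density, exclude_segments=segments)
    pos_list.append(gel)
    amp_list.append(gel_amplitude * rng.normal(1.0, 0.3, len(gel)).clip(0.1))
    lab_list.append(np.full(len(gel), LABEL_GEL, np.int8))
    seg_idx.append(np.full(len(gel), -1, np.int32))
    ax_off.append(np.zeros(len(gel)))
    rad_off.append(np.zeros((len(gel), 3)))

    pos = np.vstack(pos_list)
    if np.any(pos[:, 2] < 0):
        raise ValueError("vessel geometry extends above the array plane")
    return Phantom(
        positions=pos,
        amplitudes=np.concatenate(amp_list),
        labels=np.concatenate(lab_list),
        segments=tuple(segments),
        segment_index=np.concatenate(seg_idx),
        axial_offset=np.concatenate(ax_off),
        radial_offset=np.vstack(rad_off),
        seed=seed,
    )


def make_flow_tube(
    diameter: float = 500e-6,
    depth: float = 6e-3,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
    speed: float = 0.01,
    blood_density: float = 10.0,
    gel_density: float = 5.0,
    seed: int = 0,
    fov_x: tuple[float, float] = (-4.8e-3, 4.8e-3),
    fov_y: tuple[float, float] = (-4.8e-3, 4.8e-3),
    fov_z: tuple[float, float] = (0.5e-3, 9e-3),
    length: float | None = None,
) -> Phantom:
    """Gel block with one straight flow channel.

    Defaults mirror the bench phantom: 500-um channel with 1 cm/s blood-
    mimicking flow in static gel. Densities are scatterers per mm^3 (blood
    default 10/mm^3, gel 5/mm^3).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    e = np.asarray(axis, float)
    e = e / np.linalg.norm(e)
    if length is None:
        # fit the channel inside the box along its axis through the FOV center
        spans = np.array([fov_x, fov_y, fov_z])
        center = spans.mean(axis=1)
        center[2] = depth
        half = np.inf
        for d in range(3):
            if abs(e[d]) > 1e-12:
                half = min(half, (spans[d, 1] - center[d]) / abs(e[d]), (center[d] - spans[d, 0]) / abs(e[d]))
        length = 2 * half * 0.98
    else:
        center = np.array([np.mean(fov_x), np.mean(fov_y), depth])
    p0 = center - e * length / 2
    p1 = center + e * length / 2
    if not (fov_z[0] - 1e-9 <= depth <= fov_z[1] + 1e-9):
        raise ValueError("tube outside the field of view")
    seg = FlowSegment(tuple(p0), tuple(p1), diameter / 2, speed)
    return _vessel_phantom((seg,), blood_density, gel_density, seed, fov_x, fov_y, fov_z)


@dataclass(frozen=True)
class VascularTreeSpec:
    """Parameters of the synthetic subcutaneous plexus + feeding artery."""

    n_plexus: int = 5
    plexus_depth: float = 1.0e-3
    plexus_diameter_range: tuple[float, float] = (300e-6, 800e-6)
    artery_depth: float = 4.0e-3
    artery_diameter: float = 1.0e-3
    plexus_speed: float = 5e-3
    artery_speed: float = 2e-2
    resistive_index: float = 0.57
    heart_period_s: float = 0.86
    pulsatile: bool = True
    blood_density: float = 10.0
    tissue_density: float = 5.0
    fov_x: tuple[float, float] = (-4.8e-3, 4.8e-3)
    fov_y: tuple[float, float] = (-4.8e-3, 4.8e-3)
    fov_z: tuple[float, float] = (0.3e-3, 6e-3)
    segments: tuple | None = None  # explicit override


def make_vascular_tree(spec: VascularTreeSpec | None = None, seed: int = 0) -> Phantom:
    """Branching vascular phantom: shallow plexus fed by one deep artery.

    Plexus vessels (300-800 um diameter) sit ~1 mm deep; a 1-mm artery runs at
    ~4 mm. All blood carries the pulsatile waveform ``v_mean * w(t)`` whose
    resistive index matches the spec. Static tissue speckle surrounds the
    vessels.
    """
    spec = spec or VascularTreeSpec()
    rng = np.random.default_rng(seed)
    wf = (
        PulsatileWaveform(period_s=spec.heart_period_s, resistive_index=spec.resistive_index)
        if spec.pulsatile
        else None
    )
    if spec.segments is not None:
        segments = spec.segments
    else:
        segments = []
        # deep feeding artery along y through the center
        segments.append(
            FlowSegment(
                (0.0, spec.fov_y[0] * 0.98, spec.artery_depth),
                (0.0, spec.fov_y[1] * 0.98, spec.artery_depth),
                spec.artery_diameter / 2,
                spec.artery_speed,
                wf,
            )
        )
        # plexus: near-horizontal vessels at random orientations and offsets
        for _ in range(spec.n_plexus):
            diam = rng.uniform(*spec.plexus_diameter_range)
            theta = rng.uniform(0, np.pi)
            e = np.array([np.cos(theta), np.sin(theta), 0.0])
            c = np.array(
                [
                    rng.uniform(spec.fov_x[0] * 0.5, spec.fov_x[1] * 0.5),
                    rng.uniform(spec.fov_y[0] * 0.5, spec.fov_y[1] * 0.5),
                    spec.plexus_depth + rng.uniform(-0.2e-3, 0.2e-3),
                ]
            )
            half = 0.45 * min(spec.fov_x[1] - spec.fov_x[0], spec.fov_y[1] - spec.fov_y[0])
            segments.append(
                FlowSegment(tuple(c - e * half), tuple(c + e * half), diam / 2, spec.plexus_speed, wf)
            )
        segments = tuple(segments)
    for seg in segments:
        for p in (seg.p0, seg.p1):
            if not (spec.fov_z[0] - seg.radius <= p[2] <= spec.fov_z[1] + seg.radius):
                raise ValueError("vessel outside the field of view in depth")
    return _vessel_phantom(
        tuple(segments), spec.blood_density, spec.tissue_density, seed, spec.fov_x, spec.fov_y, spec.fov_z
    )


@dataclass(frozen=True)
class StimulusProtocol:
    """Thermal-stimulus timing: baseline, cold immersion, hot immersion."""

    baseline_s: float = 30.0
    cold_s: float = 30.0
    hot_s: float = 60.0
    doppler_rate_hz: float = 0.5

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.cold_s, self.hot_s) <= 0 or self.doppler_rate_hz <= 0:
            raise ValueError("protocol durations and rate must be positive")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.cold_s + self.hot_s

    def time_grid(self) -> np.ndarray:
        n = int(round(self.total_s * self.doppler_rate_hz))
        return np.arange(n) / self.doppler_rate_hz


@dataclass(frozen=True)
class ECGTrace:
    """R-peak train (optionally with a sampled waveform) for cardiac gating."""

    r_peak_times: np.ndarray
    hr_bpm: float
    hrv_sd_bpm: float = 0.0
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, float)
        object.__setattr__(self, "r_peak_times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("r_peak_times must be strictly increasing")


def make_ecg_trace(hr_bpm: float = 69.7, duration: float = 110.0, hrv_sd_bpm: float = 0.0, seed: int = 0) -> ECGTrace:
    """Synthetic R-peak train: intervals 60/N(hr, hrv_sd), truncated positive."""
    if hr_bpm <= 0:
        raise ValueError("hr_bpm must be positive")
    rng = np.random.default_rng(seed)
    times = []
    t = 0.0
    while t <= duration:
        times.append(t)
        bpm = rng.normal(hr_bpm, hrv_sd_bpm) if hrv_sd_bpm > 0 else hr_bpm
        bpm = max(bpm, 1e-3)
        t += 60.0 / bpm
    return ECGTrace(np.asarray(times), hr_bpm, hrv_sd_bpm)


def hrf_kernel_params_from_timing(rise_time_s: float, duration_sd_s: float) -> tuple[float, float]:
    """Gamma (shape, scale) whose mode is ``rise_time`` and SD is ``duration``.

    mode = (a - 1) b and SD = sqrt(a) b give a closed form for a single gamma
    lobe: sqrt(a) solves sqrt(a)^2 - (rise/duration) sqrt(a) - 1 = 0.
    """
    if rise_time_s <= 0 or duration_sd_s <= 0:
        raise ValueError("timings must be positive")
    rho = rise_time_s / duration_sd_s
    sqrt_a = (rho + np.sqrt(rho**2 + 4.0)) / 2.0
    a = sqrt_a**2
    b = rise_time_s / (a - 1.0)
    return float(a), float(b)


def make_stimulus_pbv(
    protocol: StimulusProtocol | None = None,
    rise_time_s: float = 14.3,
    duration_sd_s: float = 8.4,
    hot_gain: float = 1.13,
    cold_dip: float = 0.27,
    cold_rise_s: float = 3.0,
    cold_sd_s: float = 3.0,
    noise_sd: float = 0.0,
    n_voxels: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulated per-voxel PBV series for the thermal protocol, plus truth.

    The hot response is a gamma kernel (mode = ``rise_time_s``, SD =
    ``duration_sd_s``) convolved with the hot-onset step, scaled so the
    plateau reaches ``1 + hot_gain``; the cold phase is a transient gamma dip
    of fractional depth ``cold_dip``. Gaussian noise of SD ``noise_sd``
    (fraction of baseline) is added per voxel. Returns ``(t, pbv, truth)``
    where ``pbv`` has shape (n_voxels, n_t) and ``truth`` carries the
    noiseless series and generating parameters.
    """
    protocol = protocol or StimulusProtocol()
    t = protocol.time_grid()
    dt = 1.0 / protocol.doppler_rate_hz
    t_cold = protocol.baseline_s
    t_hot = protocol.baseline_s + protocol.cold_s

    a1, b1 = hrf_kernel_params_from_timing(rise_time_s, duration_sd_s)
    tau = np.arange(0, protocol.total_s + dt, dt)
    h_hot = _gamma.pdf(tau, a1, scale=b1)
    step_hot = (t >= t_hot).astype(float)
    resp_hot = np.convolve(step_hot, h_hot)[: t.size] * dt

    # cold phase: a transient gamma-shaped dip of unit depth starting at cold onset
    a_c, b_c = hrf_kernel_params_from_timing(cold_rise_s, cold_sd_s)
    h_cold = _gamma.pdf(np.clip(t - t_cold, 0, None), a_c, scale=b_c)
    resp_cold = np.where(t >= t_cold, h_cold / _gamma.pdf((a_c - 1) * b_c, a_c, scale=b_c), 0.0)

    clean = 1.0 + hot_gain * resp_hot - cold_dip * resp_cold
    rng = np.random.default_rng(seed)
    pbv = clean[None, :] + (rng.normal(0.0, noise_sd, (n_voxels, t.size)) if noise_sd > 0 else 0.0)
    truth = {
        "clean": clean,
        "rise_time_s": rise_time_s,
        "duration_sd_s": duration_sd_s,
        "hot_gain": hot_gain,
        "cold_dip": cold_dip,
        "gamma_shape": a1,
        "gamma_scale": b1,
        "t_hot": t_hot,
        "t_cold": t_cold,
    }
    return t, np.atleast_2d(pbv), truth
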