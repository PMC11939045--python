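"""Numba kernels for RF synthesis and delay-and-sum beamforming.

These loops dominate the runtime of the whole chain; everything else in the
package is thin numpy/scipy code. All geometry here is 2-D per orientation:
``u`` is the coordinate along the transmitting array's element-position axis,
``w`` along the receiving array's. Strip elements are delay-invariant along
their long axis, so distances are always computed in the (u, z) or (w, z)
plane.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

TX_PLANE_WAVE = 0
TX_ELEMENTS = 1


@njit(cache=True, fastmath=True)
def _directivity(sin_t: float, cos_t: float, width_over_lambda: float) -> float:
    """Far-field strip-element gain |sinc(w sin(t)/lambda)| * cos(t), 1 at broadside."""
    x = width_over_lambda * sin_t
    if abs(x) < 1e-12:
        s = 1.0
    else:
        px = np.pi * x
        s = np.sin(px) / px
    return abs(s) * cos_t


@njit(cache=True, fastmath=True)
def simulate_event(
    out,  # (n_rx, n_t) float64, accumulated in place
    tx_mode,  # TX_PLANE_WAVE or TX_ELEMENTS
    sin_a,
    cos_a,  # plane-wave steering (TX_PLANE_WAVE)
    t0_pw,  # min-shift of the plane-wave delay law (s)
    tx_pos,  # (n_tx,) element positions along u (TX_ELEMENTS)
    tx_pol,  # (n_tx,) float polarities (TX_ELEMENTS)
    rx_pos,  # (n_rx,) element positions along w
    scat_u,
    scat_w,
    scat_z,
    scat_amp,  # (n_scat,)
    c,
    fs,
    pulse,  # sampled effective two-way waveform
    fs_pulse,  # its (oversampled) rate
    width_over_lambda,
    use_directivity,
):
    n_rx = rx_pos.shape[0]
    n_t = out.shape[1]
    n_scat = scat_u.shape[0]
    n_ps = pulse.shape[0]
    T = (n_ps - 1) / fs_pulse
    n_pulse = int(np.ceil(T * fs)) + 2

    for k in range(n_scat):
        u = scat_u[k]
        w = scat_w[k]
        z = scat_z[k]
        a0 = scat_amp[k]
        if a0 == 0.0:
            continue

        # Transmit legs: (delay, weight) pairs.
        if tx_mode == TX_PLANE_WAVE:
            n_legs = 1
        else:
            n_legs = tx_pos.shape[0]

        for m in range(n_legs):
            if tx_mode == TX_PLANE_WAVE:
                tau_tx = (u * sin_a + z * cos_a) / c + t0_pw
                amp_tx = a0
                if use_directivity:
                    amp_tx *= _directivity(sin_a, cos_a, width_over_lambda)
            else:
                pol = tx_pol[m]
                if pol == 0.0:
                    continue
                du = u - tx_pos[m]
                r = np.sqrt(du * du + z * z)
                tau_tx = r / c
                amp_tx = a0 * pol
                if use_directivity and r > 0.0:
                    amp_tx *= _directivity(du / r, z / r, width_over_lambda)

            for j in range(n_rx):
                dw = w - rx_pos[j]
                rr = np.sqrt(dw * dw + z * z)
                tau = tau_tx + rr / c
                amp = amp_tx
                if use_directivity and rr > 0.0:
                    amp *= _directivity(dw / rr, z / rr, width_over_lambda)
                i0 = int(np.ceil(tau * fs))
                if i0 < 0:
                    i0 = 0
                i1 = i0 + n_pulse
                if i1 > n_t:
                    i1 = n_t
                for i in range(i0, i1):
                    t = i / fs - tau
                    if t < 0.0 or t >= T:
                        continue
                    idx = t * fs_pulse
                    k0 = int(idx)
                    f = idx - k0
                    out[j, i] += amp * (pulse[k0] * (1.0 - f) + pulse[k0 + 1] * f)


@njit(cache=True, fastmath=True, parallel=False)
def das_event(
    bb,  # (n_rx, n_t) complex128 baseband sampled at fs, t = n/fs
    tau_tx,  # (nu, nz) transmit arrival delay at (u, z)
    ph_tx,  # (nu, nz) complex128 exp(+i 2 pi f0 tau_tx)
    tau_rx,  # (n_rx, nw, nz) receive delay
    ph_rx_apod,  # (n_rx, nw, nz) complex128 apod * exp(+i 2 pi f0 tau_rx)
    fs,
    t_lag,  # envelope-lag compensation added to the sampling time (s)
    out,  # (nu, nw, nz) complex128, accumulated in place
):
    n_rx, n_t = bb.shape
    nu, nz = tau_tx.shape
    nw = tau_rx.shape[1]
    for iu in range(nu):
        for iw in range(nw):
            for iz in range(nz):
                acc = 0.0 + 0.0j
                tt = tau_tx[iu, iz] + t_lag
                for j in range(n_rx):
                    a = ph_rx_apod[j, iw, iz]
                    if a == 0.0:
                        continue
                    idx = (tt + tau_rx[j, iw, iz]) * fs
                    i0 = int(idx)
                    if i0 < 0 or i0 >= n_t - 1:
                        continue
                    f = idx - i0
                    s = bb[j, i0] * (1.0 - f) + bb[j, i0 + 1] * f
                    acc += a * s
                out[iu, iw, iz] += acc * ph_tx[iu, iz]
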