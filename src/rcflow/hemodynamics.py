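"""Stimulus-response analysis of power-Doppler time series.

Peripheral blood volume (PBV) is tracked as the percent change of ROI power
Doppler from its baseline. Voxelwise correlation with the thermal-stimulus
regressor is converted to an approximately unit-normal statistic with the
Fisher z-transformation, thresholded with a Bonferroni correction whose test
count is the imaging volume divided by the PSF volume. The hemodynamic
response is modeled as a difference-of-gamma kernel convolved with the
stimulus step ("cumulative difference of gamma" for a Heaviside input); the
rise time is the kernel's mode and the duration its SD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .phantoms import StimulusProtocol, hrf_kernel_params_from_timing

__all__ = [
    "HRFFit",
    "pbv_series",
    "stimulus_regressor",
    "zscore_map",
    "bonferroni_threshold",
    "gamma_diff_response",
    "fit_hrf",
    "group_stats",
]


@dataclass(frozen=True)
class HRFFit:
    """Difference-of-gamma hemodynamic response parameters.

    Kernel: ``h(tau) = gpdf(tau; a1, b1) - w * gpdf(tau; a2, b2)`` (shape /
    scale parameterization); the response to a stimulus series is
    ``baseline + amplitude * (stimulus (*) h) * dt``. ``rise_time_s`` is the
    argmax of h and ``duration_sd_s`` the SD of its normalized positive
    part. Optional ``cold_*`` fields describe a short transient dip tied to
    the cold phase of the protocol.
    """

    a1: float = 4.7
    b1: float = 3.9
    a2: float = 9.0
    b2: float = 1.6
    w: float = 0.0
    amplitude: float = 1.0
    baseline: float = 1.0
    cold_amplitude: float = 0.0
    cold_a: float = 2.0
    cold_b: float = 3.0
    rss: float = np.nan

    def kernel(self, tau: np.ndarray) -> np.ndarray:
        h = stats.gamma.pdf(tau, self.a1, scale=self.b1)
        if self.w > 0:
            h = h - self.w * stats.gamma.pdf(tau, self.a2, scale=self.b2)
        return h

    @property
    def rise_time_s(self) -> float:
        tau = np.linspace(0, 10 * self.a1 * self.b1, 20001)
        return float(tau[np.argmax(self.kernel(tau))])

    @property
    def duration_sd_s(self) -> float:
        tau = np.linspace(0, 10 * self.a1 * self.b1, 20001)
        h = np.clip(self.kernel(tau), 0, None)
        norm = np.trapezoid(h, tau)
        if norm == 0:
            return np.nan
        mu = np.trapezoid(tau * h, tau) / norm
        var = np.trapezoid((tau - mu) ** 2 * h, tau) / norm
        return float(np.sqrt(var))


def pbv_series(pd_frames: np.ndarray, roi: np.ndarray, baseline_window: int) -> np.ndarray:
    """Percent PBV change of the ROI-mean power Doppler from its baseline.

    ``pd_frames`` is (..., n_t) or a sequence of volumes with time last;
    ``baseline_window`` is the number of leading frames that precede any
    stimulus.
    """
    pd_frames = np.asarray(pd_frames, float)
    roi_mean = pd_frames[roi].mean(axis=0) if roi is not None else pd_frames.mean(axis=tuple(range(pd_frames.ndim - 1)))
    base = roi_mean[:baseline_window].mean()
    if base == 0:
        raise ValueError("zero baseline power")
    return 100.0 * (roi_mean - base) / base


def stimulus_regressor(protocol: StimulusProtocol) -> np.ndarray:
    """Tri-level stimulus series at the Doppler rate: 0 baseline, -1 cold, +1 hot."""
    t = protocol.time_grid()
    reg = np.zeros(t.size)
    reg[(t >= protocol.baseline_s) & (t < protocol.baseline_s + protocol.cold_s)] = -1.0
    reg[t >= protocol.baseline_s + protocol.cold_s] = 1.0
    return reg


def zscore_map(pd_series: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Voxelwise Fisher z of the correlation with the stimulus regressor.

    z = atanh(r) * sqrt(n - 3); constant voxels get z = 0.
    """
    x = np.asarray(pd_series, float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 time points")
    if regressor.size != n:
        raise ValueError("regressor length mismatch")
    xm = x - x.mean(axis=-1, keepdims=True)
    rm = regressor - regressor.mean()
    num = np.tensordot(xm, rm, axes=(-1, 0))
    den = np.sqrt((xm**2).sum(axis=-1) * (rm**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return np.arctanh(r) * np.sqrt(n - 3)


def bonferroni_threshold(alpha: float, fov_volume_mm3: float, psf_volume_mm3: float, tails: str = "one") -> float:
    """|z| threshold with the test count set to FOV volume / PSF volume."""
    if fov_volume_mm3 <= 0 or psf_volume_mm3 <= 0:
        raise ValueError("volumes must be positive")
    n_tests = fov_volume_mm3 / psf_volume_mm3
    a = alpha / n_tests
    if tails == "two":
        a = a / 2
    if a >= 1:
        import warnings

        warnings.warn("alpha/N >= 1; threshold degenerates to 0", stacklevel=2)
        return 0.0
    return float(stats.norm.ppf(1 - a))


def gamma_diff_response(t: np.ndarray, fit: HRFFit, stimulus: np.ndarray) -> np.ndarray:
    """Model PBV series: baseline + amplitude * (stimulus convolved with kernel).

    ``t`` must be uniform; for a unit step the discrete causal convolution
    is the cumulative integral of the kernel (the "cumulative difference of
    gamma"). The optional cold transient of the fit is *not* included here;
    it is a protocol-specific nuisance term handled by :func:`fit_hrf`.
    """
    t = np.asarray(t, float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0]):
        raise ValueError("time grid must be uniform")
    h = fit.kernel(t - t[0])
    conv = np.convolve(stimulus, h)[: t.size] * dt[0]
    return fit.baseline + fit.amplitude * conv


def _full_model(t, params, protocol: StimulusProtocol):
    a1, b1, amplitude, baseline, cold_amplitude, cold_a, cold_b = params
    t_hot = protocol.baseline_s + protocol.cold_s
    fit = HRFFit(a1=a1, b1=b1, w=0.0, amplitude=amplitude, baseline=baseline)
    step = (t >= t_hot).astype(float)
    model = gamma_diff_response(t, fit, step)
    if cold_amplitude != 0:
        tc = np.clip(t - protocol.baseline_s, 0, None)
        peak = stats.gamma.pdf((cold_a - 1) * cold_b, cold_a, scale=cold_b)
        dip = np.where(t >= protocol.baseline_s, stats.gamma.pdf(tc, cold_a, scale=cold_b) / peak, 0.0)
        model = model - cold_amplitude * dip
    return model


def fit_hrf(
    pbv: np.ndarray,
    protocol: StimulusProtocol,
    init: HRFFit | None = None,
    seed: int = 0,
    n_starts: int = 8,
    fit_cold: bool = True,
) -> HRFFit:
    """Fit the hemodynamic response of a full-protocol PBV series.

    Nonlinear least squares with seeded multi-start over the gamma timing
    parameters. The hot response is the gamma kernel convolved with the
    hot-onset Heaviside step; with ``fit_cold`` a short gamma-shaped dip
    locked to the cold onset absorbs the cold transient so it does not bias
    the hot-response timing. Returns the best fit with ``rise_time_s`` /
    ``duration_sd_s`` computable from the kernel.
    """
    pbv = np.asarray(pbv, float)
    t = protocol.time_grid()
    if pbv.size != t.size:
        raise ValueError("PBV series must cover the full protocol")
    init = init or HRFFit(amplitude=np.ptp(pbv) or 1.0, baseline=float(pbv[: max(1, int(protocol.baseline_s * protocol.doppler_rate_hz))].mean()))

    rng = np.random.default_rng(seed)
    if fit_cold:
        base_p = np.array(
            [init.a1, init.b1, init.amplitude, init.baseline, max(init.cold_amplitude, 0.05), init.cold_a, init.cold_b]
        )
        lb = np.array([1.05, 0.05, -np.inf, -np.inf, 0.0, 1.05, 0.05])
        ub = np.array([50.0, 60.0, np.inf, np.inf, np.inf, 30.0, 30.0])

        def expand(p):
            return p
    else:
        base_p = np.array([init.a1, init.b1, init.amplitude, init.baseline])
        lb = np.array([1.05, 0.05, -np.inf, -np.inf])
        ub = np.array([50.0, 60.0, np.inf, np.inf])

        def expand(p):
            return np.concatenate([p, [0.0, 2.0, 3.0]])

    def residuals(p):
        return _full_model(t, expand(p), protocol) - pbv

    best = None
    for k in range(n_starts):
        p0 = base_p.copy()
        if k > 0:
            jitter = rng.uniform(0.5, 1.8, size=2)
            p0[0] *= jitter[0]
            p0[1] *= jitter[1]
        p0 = np.clip(p0, lb + 1e-9, np.where(np.isfinite(ub), ub - 1e-9, p0))
        try:
            res = least_squares(residuals, p0, bounds=(lb, ub), max_nfev=4000)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("HRF fit failed to converge from any start")
    a1, b1, amplitude, baseline, cold_amplitude, cold_a, cold_b = expand(best.x)
    return HRFFit(
        a1=a1,
        b1=b1,
        w=0.0,
        amplitude=amplitude,
        baseline=baseline,
        cold_amplitude=cold_amplitude,
        cold_a=cold_a,
        cold_b=cold_b,
        rss=float(2 * best.cost),
    )


def group_stats(x: np.ndarray, y: np.ndarray, paired: bool = False) -> dict:
    """Normality check plus paired-t or Welch comparison (thin scipy wrappers)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(x.size, y.size) < 3:
        raise ValueError("need n >= 3 per sample")
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal lengths")
    sw_x = stats.shapiro(x)
    sw_y = stats.shapiro(y)
    if paired:
        test = stats.ttest_rel(x, y)
        name = "paired-t"
    else:
        test = stats.ttest_ind(x, y, equal_var=False)
        name = "welch"
    return {
        "shapiro_p": (float(sw_x.pvalue), float(sw_y.pvalue)),
        "test": name,
        "statistic": float(test.statistic),
        "p_value": float(test.pvalue),
    }
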