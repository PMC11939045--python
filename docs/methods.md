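# Methods

This note documents the models behind `rcflow`: what is simulated, what is
assumed, which knobs matter, and where the synthetic results are known to
differ from the reference measurements for this sensor class.

## Geometry and conventions

`x` is the column-element position axis, `y` the row-element axis, `z` depth
from the array plane (origin at the array center). A "rows" transmit uses
the elements positioned along `y` (strips extended along `x`) and receives
on the columns, and vice versa. Strip elements are treated as delay-
invariant along their long axis: every distance is computed in the plane
orthogonal to the strip. The reference design is 64+64 elements at 150-µm
pitch (9.6 × 9.6 mm aperture), 9.02-MHz center frequency, 100-MHz sampling,
c = 1480 m/s (λ ≈ 164 µm).

Transmit schemes: SA fires each of the 64 elements of one array in turn;
HSA fires all 64 with ±1 polarities from the rows of a Sylvester Hadamard
matrix (decoding is the exact left inverse, `(1/64)·Hᵀ`, an amplitude SNR
gain of √64); SPW steers plane waves over a symmetric 1°-step fan on one
array; OPW emits the fan on rows then on columns. Fans not fixed by the
reference sequences continue the 1°-step pattern centered on broadside
(16 angles → ±7.5°, 8 → ±3.5°). Compound frame rate is PRF divided by
transmits per frame: 64 transmits at 20 kHz → 312.5 volumes/s, so 400
frames span 1.28 s.

## Acoustic model

RF synthesis is a linear time-of-flight superposition: each scatterer
returns a delayed copy of the effective pulse, weighted by its reflectivity
and the strip-element directivity `|sinc(w·sinθ/λ)|·cosθ` on both legs.
Plane waves use the min-shifted steered delay law (first element fires at
t = 0; the beamformer uses the identical convention); SA transmits are
cylindrical waves from the active strip. There is no attenuation, no 1/r
spreading (all downstream metrics are relative), no multiple scattering,
no nonlinearity, and no element subdivision.

The effective pulse is the 2-cycle Hann-windowed burst convolved twice
(transmit and receive) with a Gaussian-envelope impulse response whose
one-way −6 dB fractional bandwidth is the measured 73%. This band limit
matters: without it the 2-cycle burst's sharp edges create off-depth
"wing" artifacts that dominate the synthetic-aperture side-lobe floor
(−25 dB instead of the observed ≈ −50 dB), and plane-wave compounding is
unrealistically well suppressed by pulse decoherence. Set
`PulseSpec(bandwidth_frac=None)` for an ideal wideband transducer.

Axial motion produces the slow-time Doppler phase 4π·f0·v/(c·framerate)
per frame as an emergent property of the delay geometry; nothing is
imposed. Scatterers are frozen within a compound frame and advanced
between frames.

## Beamforming

Per event, delay-and-sum on the voxel grid with complex baseband data:
sample at the round-trip delay plus the envelope-peak lag of the effective
pulse, rotate by `exp(+2πi·f0·τ)`. Receive uses a dynamic Hann aperture of
width z/f# (default f# = 1), normalized per voxel. Synthetic-aperture
transmits are compounded with a dynamic Hann transmit apodization
(`tx_fnumber` = 0.5, i.e. the full aperture tapered at mid-FOV) and the
per-voxel transmit weight normalized out; without this taper SA side lobes
would exceed OPW's, inverting the known scheme ordering. Plane-wave events
are compounded with an unweighted coherent mean; OPW averages the
rows-transmit and columns-transmit halves coherently, which symmetrizes
the PSF (each lateral axis is the mean of a narrow receive profile and a
wider transmit-fan profile). XDoppler instead correlates the two
half-series over slow time, cancelling noise that is incoherent between
orientations.

Default grid: λ/2 laterally, λ/4 axially; FWHMs are measured on intensity
profiles with cubic-spline sub-voxel interpolation so the grid does not
quantize them.

## Simulated PSF table: agreement and known gaps

With the model above, the bead study (point target at 4.8 mm) gives, against
the reference simulated values for the same sequences:

* SA / HSA: lateral FWHM 199 µm (ref. 193), side lobes −46 dB (ref. −50);
  HSA decoded data beamform identically to SA to 1e-8 relative.
* OPW32+32: 259 µm (ref. 237), grating response in the FOV −39 dB
  (design bound −30 dB). The fully formed pitch replica lies at
  sin⁻¹(λ/p − sin 15.5°) ≈ 56°, i.e. ~7.4 mm lateral at this depth —
  outside the 9.6-mm field of view — so the in-FOV annulus approaching the
  grating angle is what the metric evaluates.
* Sparse-angle schemes diverge systematically. OPW16/OPW8 come out 19/28%
  wider than the reference: the coherent half-sum profile is dominated by
  the wide transmit fan once the fan is much wider than the receive
  profile. SPW steered-axis widths come out 21–25% *narrower*: the
  reference values scale as ≈1.25× the diffraction limit of the angular
  aperture, a factor this geometry-plus-pulse model does not produce.
  Side-lobe levels for those schemes differ by more than the few-dB model
  accuracy, and the printed ordering "SPW16 worse than OPW16+16" cannot
  occur in a linear model (an OPW half-sum's side lobes are at most half
  the amplitude of its own fan's). The acceptance tests assert the printed
  values anyway and these entries fail, intentionally and visibly.

## Phantoms and physiological generators

All generators are pure functions of (parameters, seed). Blood and tissue
are point-scatterer clouds (defaults 10/mm³ in vessels, 5/mm³ tissue, with
denser settings used in the small test fixtures to keep speckle developed).
Vessels are straight cylindrical segments; blood advances along the axis by
the integrated flow and wraps at the segment end. A re-entering scatterer
stands in for a fresh particle from the pump: its radial offset is rotated
by a deterministic lap-dependent angle, otherwise the ensemble would be
periodic with the transit time and an SVD filter would see a low-rank blood
subspace that no physical phantom shows.

The pulsatile waveform is a raised-cosine systolic bump with an exponential
diastolic tail, floor-adjusted so (max−min)/max equals the target resistive
index (default 0.57) and normalized to unit mean. ECG R-peak trains draw
intervals from 60/N(hr, hrv). The thermal-protocol generator produces
30 s baseline / 30 s cold / 60 s hot PBV series at 0.5 Hz: the hot response
is a gamma kernel with mode 14.3 s and SD 8.4 s scaled to a +113% plateau;
the cold phase is a transient gamma-shaped dip (depth 27%) — the dip's
shape is a modeling choice, as only "a sudden short decrease" is described.

What these phantoms do not contain: attenuation and depth-dependent SNR,
bone, skin-surface curvature, probe motion, out-of-plane flow, or
non-Gaussian electronic noise. Passing tests therefore demonstrate the
correctness of the processing chain under the stated acoustic model, not
in vivo performance.

## Doppler processing

Clutter filtering zeroes modes of the Casorati SVD: in vivo rule, the first
15% of modes and the last 50. The filter is the orthogonal projection onto
the kept temporal subspace (the property tests verify idempotence of that
projector; re-running the *rule* on filtered data is not idempotent since
the cutoff is index-based). For bench phantoms whose clutter is static
(rank ≈ 1) the proportional low cutoff would eat blood as the ensemble
grows; bench studies therefore use an absolute low cutoff (6 modes) and a
tail fraction (25%, the in vivo 50-of-200 proportion), which is what makes
CNR grow with acquisition time as it does on a real bench. CNR is
10·log10(mean vessel PD / SD of background PD) with the background taken in
a gain-flat region at the vessel depth; the dynamic-aperture gain pattern
otherwise dominates the background SD.

Spectral Doppler: 30-point Hann STFT at 50% overlap, ROI-averaged over
3×3×3 voxels, Doppler frequency mapped to axial velocity c·f_d/(2f0); the
resistive index is (peak systolic − end diastolic)/peak systolic per
peak-to-peak cycle, averaged.

In the ideal linear model, Hadamard encoding delivers its full √N SNR gain,
so HSA *beats* OPW in bench CNR; on hardware, asymmetry between positive
and negative emission adds noise that reverses this. That asymmetry is not
modeled, and the corresponding ordering assertion in the acceptance tests
fails by design.

## Pulse wave

The Kasai estimator takes the phase of the lag-1 slow-time autocorrelation
of the *unfiltered* IQ series, averaged over a 3×3×3×2 kernel, mapped to
axial velocity c·framerate·Δφ/(4π·f0); it is exact for uniform sub-λ/8
translations and wraps beyond λ/4 per frame. Motion-source separation: SVD
of the Kasai Casorati matrix, five leading temporal vectors, seeded
symmetric FastICA (tanh contrast), component selection by the fraction of
Welch spectral power in 0.7–3 Hz plus its first harmonic (threshold 0.3),
sign fixed so the dominant deflection is positive. Peaks above a
median + 2·MAD threshold at ≥ 0.33 s spacing give per-beat heart rate;
PWTT pairs each deformation peak with the latest R-peak within 0.6 s, and
PWV divides the anatomical path length by the mean PWTT.

## Registration

Volumes are aligned on their vesselness-enhanced versions (multi-scale
Frangi, bright ridges), maximizing masked normalized cross-correlation over
6 DOF (ZYX Euler angles about the volume center, millimeter translations)
with bounded Powell search at two smoothing levels (σ = 2 voxels, then
full resolution; trust regions ±10°/±2.5 mm then ±2°/±0.5 mm). The
returned transform is the pullback: resampling the moving volume with it
aligns it to the fixed volume. Convergence is declared when the final NCC
reaches 0.3. Linear interpolation inside the optimizer, cubic for final
resampling.

## Hemodynamics

PBV is the percent change of ROI-mean power Doppler from the baseline mean.
The stimulus regressor is tri-level (0 baseline, −1 cold, +1 hot) so one
correlation captures both phases; per-voxel Pearson r against it becomes
z = atanh(r)·√(n−3), thresholded at the inverse-normal quantile of
α/N tests with N = FOV volume / PSF volume (multi-one-tailed rule on |z|).
The response model is a gamma-difference kernel convolved with the hot-onset
step (for a Heaviside input, the cumulative difference of gamma); rise time
is the kernel mode, duration the SD of its normalized positive part, and a
single gamma (w = 0) with shape 4.70 / scale 3.87 s realizes the default
14.3 s / 8.4 s timing. The fitter adds a short gamma-shaped dip locked to
the cold onset (weight ≥ 0) so the cold transient does not bias the
hot-response timing; with it, the noiseless generator round-trips to better
than 1% in rise time and duration. Fitting is bounded nonlinear least
squares with seeded multi-start over the timing parameters.

## Problem sizes

The default test and acceptance configurations are chosen to run on one
CPU: the PSF studies use the full 64+64 array on a ±3.2 mm × 2 mm grid at
λ/2 / λ/4 spacing (~3·10⁵ voxels, seconds per scheme); Doppler and CNR
studies use a 16+16 array at the same pitch with a 500-µm tube at 1 cm/s,
200–400 compound frames at 46.9 Hz, and denser scatterers than the
full-size defaults so the speckle stays developed in the small volume.
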