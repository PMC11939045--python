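# rcflow

3-D ultrafast Doppler processing for row-column-array (RCA) ultrasound
sensors, with a built-in linear acoustic simulator so the whole chain can be
exercised — and its reference performance figures reproduced — without
hardware.

An RCA addresses an N×N transducer with N row + N column electrodes. One
axis transmits (plane-wave fans or a synthetic aperture of single strips),
the orthogonal axis receives, and delay-and-sum beamforming recovers a full
3-D volume per compound frame. Running such a 64+64, 150-µm-pitch, ~9-MHz
sensor at kilohertz volume rates makes contrast-free microvascular imaging
possible at the skin scale: power Doppler after SVD clutter filtering maps
the subcutaneous vascular plexus, tissue-phase (Kasai) processing extracts
the mechanical pulse wave, rigid registration makes repeated volumes
comparable over months, and stimulus-locked power-Doppler changes quantify
peripheral blood-volume (PBV) hemodynamics.

The package is aimed at people building or evaluating RCA Doppler pipelines:
every processing stage is an importable, tested function, and every study in
the source material has a synthetic stand-in (bead phantom, flow tube,
pulsatile vascular tree, ECG, thermal-stimulus protocol).

## What is inside

| module | contents |
| --- | --- |
| `rcflow.sequences` | SA / HSA / SPW / OPW transmit schemes, Hadamard encode/decode, PRF arithmetic (`frame rate = PRF / transmits`) |
| `rcflow.phantoms` | bead, flow-tube and vascular-tree phantoms, pulsatile waveforms with a target resistive index, ECG trains, PBV protocol generator |
| `rcflow.simulator` | linear time-of-flight RF synthesis with strip-element directivity and the measured 73% two-way band limit |
| `rcflow.beamform` | IQ demodulation, 3-D RCA delay-and-sum with dynamic apodization, orthogonal-plane-wave compounding, XDoppler, B-mode |
| `rcflow.doppler` | skin-surface masking, SVD clutter filter (15% + last-50 rule), power / signed / spectral Doppler, resistive index |
| `rcflow.pulsewave` | Kasai phase-shift velocimetry, SVD+ICA pulse unmixing, peak detection, heart rate, Bland-Altman, PWTT / PWV |
| `rcflow.longitudinal` | Hessian vesselness, segmentation, 6-DOF NCC rigid registration, volume correlation, common-volume fraction |
| `rcflow.hemodynamics` | PBV series, Fisher-z stimulus correlation maps, Bonferroni thresholds (tests = FOV volume / PSF volume), difference-of-gamma HRF fitting |
| `rcflow.metrics` | −3 dB FWHM with sub-voxel interpolation, side/grating-lobe levels, CNR, SNR |
| `rcflow.pipeline`, `rcflow.io`, `rcflow.cli` | config-driven stage chains, HDF5/NIfTI/CSV artifacts, the `rcflow` command line |

## Worked example

Simulate the reference bead experiment (point target at 4.8 mm, 64+64 array)
with the 32+32-angle orthogonal plane-wave sequence and measure its PSF:

```bash
$ rcflow demo --scheme OPW --n-angles 32
{
  "scheme": "OPW32",
  "fwhm_x_m": 0.0002586091522833157,
  "fwhm_y_m": 0.00025860915228331576,
  "fwhm_z_m": 0.00011378556295452407,
  "fwhm_lateral_mean_m": 0.00025860915228331576,
  "fwhm_steered_m": 0.00025860915228331576,
  "side_lobe_db": -21.175135974067892,
  "grating_lobe_db": -39.49523663506622,
  "sin_range": [0.45, 0.71]
}
```

Reading the numbers: the compounded OPW32+32 point-spread function is
symmetric in x and y with a −3 dB lateral width of 259 µm (reference
simulated value for this sequence: 237 µm) and a 114-µm axial width; the
strongest side lobe sits 21 dB below the peak, and the worst in-FOV grating
response (the array pitch is just below the wavelength) is −39 dB, below the
−30 dB level the sensor was designed for.

The same study from Python:

```python
from rcflow.pipeline import psf_study
rep = psf_study("SA")             # single-element synthetic aperture
print(rep["fwhm_lateral_mean_m"]) # 1.99e-4  (199 um)
print(rep["side_lobe_db"])        # -46.2
```

A full Doppler chain on a synthetic flow phantom:

```python
from rcflow import ArraySpec, VoxelGrid, build_scheme, make_flow_tube
from rcflow.pipeline import acquire_series
from rcflow.doppler import svd_clutter_filter, power_doppler

array = ArraySpec(16, 16)                     # scaled-down sensor
phantom = make_flow_tube(diameter=500e-6, depth=2e-3, speed=0.01,
                         fov_x=(-1.2e-3, 1.2e-3), fov_y=(-1.2e-3, 1.2e-3),
                         fov_z=(1.2e-3, 2.8e-3), seed=7)
scheme = build_scheme("OPW", array, n_angles=32, prf_hz=3e3)
grid = VoxelGrid.regular((-1.2e-3, 1.2e-3), (-1.2e-3, 1.2e-3),
                         (1.4e-3, 2.6e-3), (82e-6, 82e-6, 82e-6))
series = acquire_series(phantom, scheme, grid, n_frames=200,
                        array=array, depth_max=4e-3, snr_db=10, seed=11)
filtered, singular_values = svd_clutter_filter(series)
pd = power_doppler(filtered)                  # vessel voxels ~15x background
```

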