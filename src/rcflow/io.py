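"""Artifact I/O: HDF5 containers for channel data, IQ series and phantoms,
NIfTI export for volumes, CSV for traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .beamform import IQVolumeSeries
from .core import ArraySpec, Medium, PulseSpec, VoxelGrid
from .sequences import TransmitScheme
from .simulator import ChannelData

__all__ = [
    "save_channel_data",
    "load_channel_data",
    "save_iq_series",
    "load_iq_series",
    "save_volume_nifti",
    "save_trace_csv",
    "load_trace_csv",
]


def save_channel_data(path, data: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=data.samples, compression="gzip", compression_opts=1)
        f.attrs["fs"] = data.fs
        f.attrs["prf_hz"] = data.prf_hz
        f.attrs["is_baseband"] = data.is_baseband
        f.attrs["t0"] = data.t0
        f.attrs["scheme"] = json.dumps(data.scheme.to_dict())
        f.attrs["array"] = json.dumps(
            {"n_rows": data.array.n_rows, "n_cols": data.array.n_cols, "pitch": data.array.pitch, "element_width": data.array.element_width}
        )
        f.attrs["pulse"] = json.dumps(
            {"f0": data.pulse.f0, "n_cycles": data.pulse.n_cycles, "fs": data.pulse.fs, "bandwidth_frac": data.pulse.bandwidth_frac}
        )
        f.attrs["c"] = data.medium.c


def load_channel_data(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        arr = json.loads(f.attrs["array"])
        pul = json.loads(f.attrs["pulse"])
        return ChannelData(
            samples=f["rf"][()],
            fs=float(f.attrs["fs"]),
            prf_hz=float(f.attrs["prf_hz"]),
            scheme=TransmitScheme.from_dict(json.loads(f.attrs["scheme"])),
            array=ArraySpec(**arr),
            pulse=PulseSpec(f0=pul["f0"], n_cycles=pul["n_cycles"], fs=pul["fs"], bandwidth_frac=pul["bandwidth_frac"]),
            medium=Medium(float(f.attrs["c"])),
            is_baseband=bool(f.attrs["is_baseband"]),
            t0=float(f.attrs["t0"]),
        )


def save_iq_series(path, series: IQVolumeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("iq", data=series.data, compression="gzip", compression_opts=1)
        for name, v in zip("xyz", (series.grid.x, series.grid.y, series.grid.z)):
            f.create_dataset(f"grid/{name}", data=v)
        f.attrs["framerate_hz"] = series.framerate_hz
        f.attrs["f0"] = series.f0
        f.attrs["provenance"] = series.provenance


def load_iq_series(path) -> IQVolumeSeries:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(f["grid/x"][()], f["grid/y"][()], f["grid/z"][()])
        return IQVolumeSeries(
            f["iq"][()], grid, float(f.attrs["framerate_hz"]), float(f.attrs["f0"]), str(f.attrs["provenance"])
        )


def save_volume_nifti(path, volume: np.ndarray, grid: VoxelGrid) -> None:
    """Volume to NIfTI with mm voxel sizes, axis order (x, y, z)."""
    dx, dy, dz = (s * 1e3 if s else 1.0 for s in grid.spacing)
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [grid.x[0] * 1e3, grid.y[0] * 1e3, grid.z[0] * 1e3]
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def save_trace_csv(path, times: np.ndarray, values: np.ndarray, value_name: str = "value") -> None:
    pd.DataFrame({"t_s": times, value_name: values}).to_csv(path, index=False)


def load_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
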