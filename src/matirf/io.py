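"""File formats: multi-page TIFF stacks/volumes, HDF5 volumes, angle CSVs.

Conventions: stack pages are in ascending-angle order; volume pages are in
ascending z with page 1 the coverslip-nearest slice.  Intensities are
stored as float32 (16-bit unsigned input is converted to float without
scaling).  HDF5 volumes carry the grid metadata as attributes; TIFF
volumes need the axial step from the config.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward_model import AcquisitionStack, DimensionError, FluorophoreVolume, GridSpec
from .optics import AngleSet

__all__ = [
    "read_angles_csv",
    "write_angles_csv",
    "read_stack",
    "write_stack",
    "read_volume",
    "write_volume",
]


def read_angles_csv(path) -> AngleSet:
    """One-column CSV of incident angles in degrees (header optional)."""
    angles = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                angles.append(float(row[0]))
            except ValueError:
                continue  # header line
    return AngleSet(tuple(angles))


def write_angles_csv(path, angle_set: AngleSet) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg"])
        for a in angle_set.angles_deg:
            writer.writerow([f"{a:.6f}"])


def read_stack(path, angle_set: AngleSet,
               pixel_size_nm: float = 107.0) -> AcquisitionStack:
    """Read a multi-page TIFF stack, page m <-> angle m (ascending)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(angle_set):
        raise DimensionError(
            f"stack has {data.shape[0]} pages but {len(angle_set)} angles given"
        )
    return AcquisitionStack(images=data.astype(float), angle_set=angle_set,
                            pixel_size_nm=pixel_size_nm)


def write_stack(path, stack: AcquisitionStack) -> None:
    tifffile.imwrite(path, stack.images.astype(np.float32),
                     photometric="minisblack")


def read_volume(path, grid: GridSpec | None = None) -> FluorophoreVolume:
    """Read a volume from TIFF (needs a grid for metadata) or HDF5.

    HDF5 files store the grid as attributes of the ``volume`` dataset and
    need no external grid; reading fails without a stored axial step.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["volume"]
            values = np.asarray(ds, dtype=float)
            attrs = dict(ds.attrs)
            if "dz_nm" not in attrs:
                raise DimensionError("HDF5 volume is missing dz_nm metadata")
            grid = GridSpec(
                nx=values.shape[2], ny=values.shape[1], nz=values.shape[0],
                dz_nm=float(attrs["dz_nm"]),
                pixel_size_nm=float(attrs.get("pixel_size_nm", 107.0)),
                z0_nm=float(attrs.get("z0_nm", 0.0)),
            )
        return FluorophoreVolume(grid=grid, values=values)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    if grid is None:
        raise DimensionError("TIFF volumes need grid metadata from the config")
    return FluorophoreVolume(grid=grid, values=data)


def write_volume(path, volume: FluorophoreVolume) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("volume",
                                   data=volume.values.astype(np.float32))
            ds.attrs["dz_nm"] = volume.grid.dz_nm
            ds.attrs["z0_nm"] = volume.grid.z0_nm
            ds.attrs["pixel_size_nm"] = volume.grid.pixel_size_nm
            ds.attrs["z_nm"] = volume.grid.z_centers_nm
        return
    tifffile.imwrite(path, volume.values.astype(np.float32),
                     photometric="minisblack")
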