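"""Multi-channel volume container and TIFF/HDF5 round-trip I/O."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

from .geometry import ImagingGeometry

__all__ = [
    "SYNAPTIC_CHANNELS",
    "ALL_CHANNELS",
    "MultiChannelVolume",
    "read_volume",
    "write_volume",
]

#: STORM channels carrying synaptic immunolabels, by role.
SYNAPTIC_CHANNELS = ("homer1", "bassoon", "vglut2")
#: All STORM channels, including the anterograde tracer.
ALL_CHANNELS = SYNAPTIC_CHANNELS + ("ctb",)


@dataclass
class MultiChannelVolume:
    """Aligned multi-channel voxel stack with physical geometry.

    ``channels`` maps role names (homer1/bassoon/vglut2/ctb) to ``(nz, ny,
    nx)`` uint8 arrays of rendered super-resolution intensity.
    ``conventional`` holds the diffraction-limited counterpart of each
    channel, used as a coarse background mask during segmentation.
    ``section_ids`` identifies the physical section of each z-plane.
    """

    geometry: ImagingGeometry
    channels: dict[str, np.ndarray]
    conventional: dict[str, np.ndarray] = field(default_factory=dict)
    section_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        grid = self.geometry.grid_shape
        for name, arr in {**self.channels, **self.conventional}.items():
            if arr.shape != grid:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, expected {grid}"
                )
        if not self.section_ids:
            self.section_ids = list(range(grid[0]))
        if len(self.section_ids) != grid[0]:
            raise ValueError("section_ids length must equal number of z planes")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"missing channel {name!r}")
        return self.channels[name]


def write_volume(path: str, volume: MultiChannelVolume) -> None:
    """Write a volume to one HDF5 container or a directory of per-channel TIFFs.

    HDF5 layout: ``/channels/<name>`` and ``/conventional/<name>`` uint8
    datasets plus geometry attributes.  A path ending in ``.h5``/``.hdf5``
    selects HDF5; any other path is treated as a directory and receives one
    multi-page TIFF per channel (page = section).
    """
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            g = f.create_group("channels")
            for name, arr in volume.channels.items():
                g.create_dataset(name, data=arr)
            c = f.create_group("conventional")
            for name, arr in volume.conventional.items():
                c.create_dataset(name, data=arr)
            f.attrs["voxel_xy_nm"] = volume.geometry.voxel_xy
            f.attrs["voxel_z_nm"] = volume.geometry.voxel_z
            f.attrs["shape_xyz"] = np.asarray(volume.geometry.shape)
            f.attrs["bit_depth"] = volume.geometry.bit_depth
            f.attrs["section_ids"] = np.asarray(volume.section_ids)
    else:
        os.makedirs(path, exist_ok=True)
        meta = dict(
            voxel_xy_nm=volume.geometry.voxel_xy,
            voxel_z_nm=volume.geometry.voxel_z,
            bit_depth=volume.geometry.bit_depth,
        )
        for name, arr in volume.channels.items():
            tifffile.imwrite(
                os.path.join(path, f"{name}.tif"), arr, metadata=meta
            )
        for name, arr in volume.conventional.items():
            tifffile.imwrite(
                os.path.join(path, f"conv_{name}.tif"), arr, metadata=meta
            )


def read_volume(
    path: str, geometry: ImagingGeometry | None = None
) -> MultiChannelVolume:
    """Read a volume written by :func:`write_volume`.

    The HDF5 container is self-describing.  For a TIFF directory the
    geometry must be supplied (TIFF metadata does not round-trip voxel
    sizes reliably across writers).
    """
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            if "channels" not in f:
                raise ValueError("HDF5 file has no /channels group")
            channels = {name: f["channels"][name][()] for name in f["channels"]}
            for name in ALL_CHANNELS:
                if name not in channels:
                    raise ValueError(f"HDF5 file missing /channels/{name}")
            conventional = {}
            if "conventional" in f:
                conventional = {
                    name: f["conventional"][name][()] for name in f["conventional"]
                }
            geometry = ImagingGeometry(
                voxel_xy=float(f.attrs["voxel_xy_nm"]),
                voxel_z=float(f.attrs["voxel_z_nm"]),
                shape=tuple(int(v) for v in f.attrs["shape_xyz"]),
                bit_depth=int(f.attrs["bit_depth"]),
            )
            section_ids = [int(v) for v in f.attrs["section_ids"]]
        return MultiChannelVolume(geometry, channels, conventional, section_ids)

    if geometry is None:
        raise ValueError("geometry is required to read a TIFF directory")
    channels = {}
    conventional = {}
    for name in ALL_CHANNELS:
        fp = os.path.join(path, f"{name}.tif")
        if not os.path.exists(fp):
            raise ValueError(f"TIFF directory missing channel {name!r}")
        channels[name] = tifffile.imread(fp)
        cfp = os.path.join(path, f"conv_{name}.tif")
        if os.path.exists(cfp):
            conventional[name] = tifffile.imread(cfp)
    return MultiChannelVolume(geometry, channels, conventional)
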