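"""Multi-channel 3D intensity volumes and TIFF I/O.

A :class:`VolumeImage` is the raw unit of input for the whole pipeline: a
``(C, Z, Y, X)`` intensity grid together with its (possibly anisotropic)
voxel spacing in micrometres and the role of each channel.  Physical
coordinates throughout the package are ``(z, y, x)`` vectors in µm, with
voxel centres at ``index * voxel_size`` (0-indexed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: canonical channel roles, in storage order
CHANNEL_ROLES = ("protein_a", "protein_b", "membrane")

#: conventional excitation wavelengths (nm) for each role
ROLE_WAVELENGTHS = {"protein_a": 488, "protein_b": 561, "membrane": 660}


@dataclass
class VolumeImage:
    """A multi-channel 3D confocal stack.

    Parameters
    ----------
    data
        Intensities, shape ``(C, Z, Y, X)`` (a single-channel ``(Z, Y, X)``
        array is promoted).
    voxel_size
        ``(dz, dy, dx)`` voxel spacing in µm.
    channels
        Role name per channel, e.g. ``("protein_a", "membrane")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: tuple[str, ...] = field(default=("protein_a",))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel size {self.voxel_size}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels in data but {len(self.channels)} names"
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> np.ndarray:
        """Physical position of the last voxel centre per axis (µm)."""
        return (np.array(self.shape_zyx) - 1) * np.array(self.voxel_size)

    def channel(self, role: str) -> np.ndarray:
        """Return one channel as a ``(Z, Y, X)`` array."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(f"channel {role!r} not present (have {self.channels})") from None
        return self.data[idx]

    def has_channel(self, role: str) -> bool:
        return role in self.channels


def save_tiff(path, volume: VolumeImage) -> None:
    """Write a volume as an ImageJ-style multi-page TIFF with voxel metadata."""
    dz, dy, dx = volume.voxel_size
    # ImageJ hyperstack axis order is TZCYXS; we store ZCYX
    data = np.moveaxis(volume.data, 0, 1)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
            "Info": json.dumps({"channels": list(volume.channels)}),
        },
    )


def load_tiff(path, channels: tuple[str, ...] | None = None,
              voxel_size: tuple[float, float, float] | None = None) -> VolumeImage:
    """Read a multi-page TIFF written by :func:`save_tiff` (or compatible).

    ``channels`` / ``voxel_size`` override whatever metadata the file carries;
    both are required if the file carries none.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.imagej_metadata or {}
        dz = meta.get("spacing")
        dy = dx = None
        page = tif.pages[0]
        if "XResolution" in page.tags and "YResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                dx = den / num
            num, den = page.tags["YResolution"].value
            if num:
                dy = den / num
        file_channels = None
        info = meta.get("Info")
        if info:
            try:
                file_channels = tuple(json.loads(info)["channels"])
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]  # Z,Y,X -> Z,C,Y,X
    data = np.moveaxis(arr, 1, 0)
    if channels is None:
        channels = file_channels
    if channels is None:
        channels = CHANNEL_ROLES[: data.shape[0]]
    if voxel_size is None:
        if dz is None or dy is None or dx is None:
            raise ValueError(f"{path}: no voxel-size metadata; pass voxel_size explicitly")
        voxel_size = (float(dz), float(dy), float(dx))
    return VolumeImage(data=data, voxel_size=voxel_size, channels=tuple(channels))
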