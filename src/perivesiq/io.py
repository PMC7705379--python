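"""Calibrated multi-channel 3D image stack I/O and bit-depth conversion.

Stacks are stored as (channel, z, y, x) arrays with a physical voxel size
in nanometres. TIFF round-trips go through :mod:`tifffile` using ImageJ
metadata so that channel names and calibration survive write/read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Raised when a stack has no voxel calibration and none was supplied."""


class ShapeError(ValueError):
    """Raised when image data is not a 3D (or channel + 3D) array."""


@dataclass(frozen=True)
class ImageStack:
    """A calibrated multi-channel 3D voxel grid.

    Parameters
    ----------
    voxels : ndarray, shape (c, z, y, x)
        Non-negative intensities, one 3D grid per channel.
    channels : tuple of str
        Channel names, e.g. ``("UEA_I", "CLN5")``.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in nanometres; all positive.
    bit_depth : {8, 16}
        Nominal intensity range, 0..255 or 0..65535.
    """

    voxels: np.ndarray
    channels: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 3:
            v = v[np.newaxis]
        if v.ndim != 4:
            raise ShapeError(f"expected (c, z, y, x) voxels, got ndim={v.ndim}")
        if len(self.channels) != v.shape[0]:
            raise ShapeError(
                f"{len(self.channels)} channel names for {v.shape[0]} channels"
            )
        dx, dy, dz = self.voxel_size
        if not (dx > 0 and dy > 0 and dz > 0):
            raise CalibrationError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "voxels", np.ascontiguousarray(v, dtype=dtype))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "voxel_size", (float(dx), float(dy), float(dz)))

    @property
    def shape(self) -> tuple[int, int, int]:
        """(z, y, x) grid shape."""
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        dx, dy, dz = self.voxel_size
        return (dx / 1000.0) * (dy / 1000.0) * (dz / 1000.0)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's (z, y, x) voxel grid by name."""
        try:
            i = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None
        return self.voxels[i]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` to a TIFF with calibration metadata.

    Channel names and the (dx, dy, dz) voxel size in nm are embedded in the
    ImageJ description so :func:`read_stack` restores them losslessly.
    """
    path = Path(path)
    dx, dy, dz = stack.voxel_size
    # tifffile's ImageJ writer wants (z, c, y, x); resolution is px per unit
    data = np.moveaxis(stack.voxels, 0, 1)
    meta = {
        "axes": "ZCYX",
        "spacing": dz / 1000.0,  # μm between z sections
        "unit": "um",
        "Labels": list(stack.channels),
        "Info": json.dumps(
            {"voxel_size_nm": [dx, dy, dz], "channels": list(stack.channels)}
        ),
    }
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1000.0 / dx, 1000.0 / dy),  # pixels per μm
        metadata=meta,
    )


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack with calibration.

    Parameters
    ----------
    path : path-like
        TIFF file, expected to hold a 3D single- or multi-channel stack.
    voxel_size_override : (dx, dy, dz) in nm, optional
        Used when the file carries no resolution metadata; also wins over
        file metadata when given.

    Raises
    ------
    CalibrationError
        No calibration in the file and no override supplied.
    ShapeError
        Data is not 3D (optionally with a channel axis).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ij = tf.imagej_metadata or {}

    channels: list[str] | None = None
    voxel_size: tuple[float, float, float] | None = None
    info = ij.get("Info")
    if info:
        try:
            d = json.loads(info)
            voxel_size = tuple(d["voxel_size_nm"])  # type: ignore[assignment]
            channels = list(d["channels"])
        except (json.JSONDecodeError, KeyError, TypeError):
            pass

    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)  # type: ignore[assignment]
    if voxel_size is None:
        raise CalibrationError(
            f"{path}: no voxel calibration in metadata and no override given"
        )

    # normalise axes to (c, z, y, x)
    if data.ndim == 3:
        data = data[np.newaxis]
    elif data.ndim == 4:
        if axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
        elif axes == "CZYX":
            pass
        else:  # fall back: assume smaller of first two axes is channels
            if data.shape[0] > data.shape[1]:
                data = np.moveaxis(data, 1, 0)
    else:
        raise ShapeError(f"{path}: expected 3D or 4D data, got shape {data.shape}")

    if channels is None or len(channels) != data.shape[0]:
        channels = [f"ch{i}" for i in range(data.shape[0])]

    bit_depth = 8 if data.dtype == np.uint8 else 16
    return ImageStack(
        voxels=data, channels=tuple(channels), voxel_size=voxel_size, bit_depth=bit_depth
    )


def to_8bit(stack: ImageStack) -> ImageStack:
    """Convert a stack to 8-bit by per-channel linear min–max rescale.

    Each channel is mapped so its minimum goes to 0 and its maximum to 255,
    with rounding half-up. A constant channel maps to all zeros. 8-bit input
    is returned unchanged.
    """
    if stack.bit_depth == 8:
        return stack
    out = np.empty_like(stack.voxels, dtype=np.uint8)
    for i in range(stack.n_channels):
        ch = stack.voxels[i].astype(np.float64)
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            out[i] = 0
        else:
            scaled = 255.0 * (ch - lo) / (hi - lo)
            out[i] = np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
    return replace(stack, voxels=out, bit_depth=8)
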