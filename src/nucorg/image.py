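"""Raster container and TIFF volume I/O.

All arrays in this package are 3D scalar grids in ``(z, y, x)`` axis order
(the natural page order of a confocal z-stack saved as TIFF), and every
physical quantity — voxel spacing, coordinates, distances — is expressed in
micrometres, also in ``(z, y, x)`` order.  The physical coordinate of voxel
``(k, j, i)`` is ``(k*sz, j*sy, i*sx)``, i.e. the origin sits at the centre
of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """One channel's 3D voxel grid with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Scalar intensities (any numeric dtype).
    spacing : tuple of float
        Micrometres per voxel along ``(z, y, x)``.  Confocal stacks are
        typically anisotropic (z step larger than the xy pixel).
    channel : str
        Free-form channel label (e.g. ``"dna"``, ``"rsat1"``).
    provenance : str
        Where the data came from — a file path or a phantom identifier.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if any(n < 2 for n in self.values.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        sz, sy, sx = self.spacing
        return sz * sy * sx


def read_stack(
    path: str | os.PathLike,
    spacing_override: tuple[float, float, float] | None = None,
    channel: str = "",
) -> ImageStack:
    """Read a 3D TIFF volume (z-major page order).

    Spacing resolution order: explicit ``spacing_override``, else ImageJ-style
    TIFF metadata (``spacing`` tag for z, x/y resolution tags for the pixel
    size).  If neither source provides it, raise.
    """
    path = os.fspath(path)
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        meta = tf.imagej_metadata or {}
        spacing = None
        if spacing_override is not None:
            spacing = tuple(float(s) for s in spacing_override)
        elif "spacing" in meta:
            sz = float(meta["spacing"])
            page = tf.pages[0]
            try:
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                sx = xres[1] / xres[0]
                sy = yres[1] / yres[0]
            except (KeyError, ZeroDivisionError):
                raise ValueError(f"{path}: z spacing present but xy resolution missing")
            spacing = (sz, sy, sx)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing in metadata and no override given")
    return ImageStack(values, spacing, channel=channel, provenance=path)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a 3D volume as an ImageJ-compatible TIFF with spacing metadata."""
    sz, sy, sx = stack.spacing
    values = stack.values
    if values.dtype not in (np.uint8, np.uint16, np.float32):
        values = values.astype(np.float32)
    tifffile.imwrite(
        os.fspath(path),
        values,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
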