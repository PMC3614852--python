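"""Volume assembly and inter-slice interpolation.

A :class:`Volume` is a voxel-centered scalar field D(x_i, y_j, z_k) with
per-axis spacings in mm.  Slice stacks are anisotropic (inter-slice distance
typically exceeds pixel size); :func:`interpolate_to_isotropic` inserts
linearly interpolated slices so the grid becomes homogeneous in each
dimension before isosurfacing.  For binary masks, shape-based interpolation
(linear interpolation of per-slice signed Euclidean distance transforms)
keeps intermediate cross-sections geometrically plausible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .formats import FormatError, SliceStack

logger = logging.getLogger(__name__)

#: Default isovalue for reconstructing masked 8-bit stacks (background 0).
DEFAULT_ISOVALUE = 127.5


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    ``data`` is indexed ``data[z, y, x]``; the physical position of sample
    (ix, iy, iz) is ``origin + (ix*dx, iy*dy, iz*dz)`` with
    ``spacing = (dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got {self.data.ndim}D")
        if any(s < 4 for s in self.data.shape):
            raise FormatError(f"every volume dimension must be >= 4, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacings must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        """(nx, ny, nz)."""
        nz, ny, nx = self.data.shape
        return nx, ny, nz

    def sample_position(self, ix: int, iy: int, iz: int) -> np.ndarray:
        dx, dy, dz = self.spacing
        ox, oy, oz = self.origin
        return np.array([ox + ix * dx, oy + iy * dy, oz + iz * dz])


def stack_to_volume(stack: SliceStack, masks: Sequence[np.ndarray] | None = None) -> Volume:
    """Assemble a (registered) stack into a Volume, optionally masked.

    Where a mask is 0 the voxel value is 0 (background); elsewhere the slice
    luminance is kept.  Spacings are (pixel_size, pixel_size, slice_spacing).
    """
    data = stack.as_array()
    if masks is not None:
        if len(masks) != len(stack):
            raise FormatError(f"mask count {len(masks)} != slice count {len(stack)}")
        for i, m in enumerate(masks):
            if np.asarray(m).shape != stack.shape:
                raise FormatError(
                    f"mask {i} shape {np.asarray(m).shape} mismatches slice shape {stack.shape}"
                )
        mask_arr = np.stack([np.asarray(m) != 0 for m in masks], axis=0)
        data = np.where(mask_arr, data, 0.0)
    return Volume(
        data=data,
        spacing=(stack.pixel_size, stack.pixel_size, stack.slice_spacing),
        origin=(0.0, 0.0, 0.0),
    )


def threshold_mask(stack: SliceStack, low: float, high: float) -> list[np.ndarray]:
    """Binary masks: 1 where low <= value <= high (inclusive both ends)."""
    if low > high:
        raise FormatError(f"threshold window low {low} > high {high}")
    return [((im >= low) & (im <= high)).astype(np.uint8) for im in stack.images]


def _new_z_grid(volume: Volume) -> tuple[np.ndarray, float]:
    dx, dy, dz = volume.spacing
    if abs(dx - dy) > 1e-12:
        raise FormatError(
            f"in-plane spacings differ (dx={dx}, dy={dy}); resample in-plane first"
        )
    if dz < min(dx, dy) - 1e-12:
        raise FormatError(f"slice spacing {dz} already finer than pixel size {dx}")
    nz = volume.data.shape[0]
    new_dz = dx
    n_new = int(round((nz - 1) * dz / new_dz)) + 1
    positions = np.arange(n_new) * new_dz
    return positions, new_dz


def interpolate_to_isotropic(volume: Volume, method: str = "linear") -> Volume:
    """Resample along z to isotropic spacing dz' = dx.

    ``method='linear'`` interpolates intensities between adjacent slices;
    ``method='shape'`` treats slices as a segmentation (nonzero = inside)
    and interpolates their per-slice signed Euclidean distance transforms,
    re-thresholding at 0, so interpolated cross-sections follow the
    segmented shape; inserted slices take the volume's foreground level.
    Original slice planes that land on the new grid are copied exactly.
    """
    if method not in ("linear", "shape"):
        raise FormatError(f"unknown interpolation method {method!r}")
    dx, dy, dz = volume.spacing
    if abs(dz - dx) < 1e-12 and abs(dx - dy) < 1e-12:
        return Volume(volume.data.copy(), volume.spacing, volume.origin)
    positions, new_dz = _new_z_grid(volume)
    nz = volume.data.shape[0]

    if method == "shape":
        field3d = np.stack([_signed_edt(sl) for sl in volume.data], axis=0)
        level = float(volume.data.max()) or 1.0
    else:
        field3d = volume.data

    out = np.empty((len(positions),) + volume.data.shape[1:])
    t = positions / dz
    for i, ti in enumerate(t):
        ti = min(max(ti, 0.0), nz - 1)
        k = int(np.floor(ti))
        frac = ti - k
        if frac < 1e-9 or k == nz - 1:
            out[i] = volume.data[k]  # original slice plane: exact copy
        elif frac > 1 - 1e-9:
            out[i] = volume.data[k + 1]
        else:
            v = (1 - frac) * field3d[k] + frac * field3d[k + 1]
            out[i] = level * (v >= 0) if method == "shape" else v
    return Volume(out, spacing=(dx, dy, new_dz), origin=volume.origin)


def _signed_edt(mask_slice: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance transform: positive inside, negative outside."""
    m = mask_slice != 0
    if not m.any():
        return np.full(m.shape, -np.inf)
    if m.all():
        return np.full(m.shape, np.inf)
    inside = ndimage.distance_transform_edt(m)
    outside = ndimage.distance_transform_edt(~m)
    return inside - outside


# ---------------------------------------------------------------------------
# serialization: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as a multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    sidecar = {
        "spacing_mm": list(volume.spacing),
        "origin_mm": list(volume.origin),
        "shape_zyx": list(volume.data.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sc_path = path.with_suffix(path.suffix + ".json")
    if sc_path.exists():
        sc = json.loads(sc_path.read_text())
        return Volume(data, spacing=tuple(sc["spacing_mm"]), origin=tuple(sc["origin_mm"]))
    logger.warning("no sidecar for %s; assuming unit spacing", path)
    return Volume(data, spacing=(1.0, 1.0, 1.0))
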