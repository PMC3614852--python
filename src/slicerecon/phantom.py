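"""Synthetic anatomical phantoms.

Analytic solids (sphere, torus, tube) are sampled into signed-distance
volumes and rendered into 8-bit slice stacks that emulate cryosection
photograph stacks: bright tissue on dark background, fiducial marker disks
replicated on every slice, optional per-slice affine jitter, additive
Gaussian sensor noise.  Because the geometry is analytic, every pipeline
stage can be tested against exact ground truth without external data.

Rendered intensity levels are quantized on purpose (background 0, fiducial
rods 100, solid interior 255, no antialiasing): a single threshold window
then cleanly separates solid, background and markers, and noise or
resampling cannot smear one class into another.  Noise is added after
rasterization, never to geometry, so the recorded truth stays exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .formats import SliceStack, write_mask_stack, write_stack
from .registration import Affine2D, resample_slice
from .volume import Volume

logger = logging.getLogger(__name__)

#: Rendered intensity levels (8-bit).  The solid renders at full scale so
#: the level midpoint equals the default reconstruction isovalue 127.5;
#: fiducial rods render at a distinct darker gray so a single intensity
#: window separates rods from solid and background.
BACKGROUND_LEVEL = 0.0
INSIDE_LEVEL = 255.0
FIDUCIAL_LEVEL = 100.0

#: Number of centerline samples used for tube distances (approximate; a
#: phantom does not need an exact tube SDF).
TUBE_CENTERLINE_SAMPLES = 1000


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass
class PhantomSpec:
    """Specification of a synthetic solid sampled on a voxel grid.

    ``shape_params`` in mm: sphere expects ``center`` (optional, defaults to
    the grid center) and ``radius``; torus expects ``center``,
    ``major_radius``, ``minor_radius`` (tube axis along z); tube expects
    ``control_points`` (a list of 3D points interpolated by a cubic spline)
    and ``radius``.  ``fiducials`` are (x_mm, y_mm, radius_mm) disks
    replicated on every slice.  ``jitter`` is an optional per-slice list of
    :class:`Affine2D` (pixel coordinates).  Identical spec + seed produces
    bit-identical output.
    """

    shape_kind: str
    shape_params: dict
    grid_shape: tuple[int, int, int] = (32, 32, 32)  # (nx, ny, nz)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 0.0
    fiducials: list[tuple[float, float, float]] = field(default_factory=list)
    jitter: list[Affine2D] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "torus", "tube"):
            raise PhantomError(f"unknown shape kind {self.shape_kind!r}")
        if any(int(n) < 4 for n in self.grid_shape):
            raise PhantomError(f"grid_shape components must be >= 4, got {self.grid_shape}")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacings must be > 0, got {self.spacing}")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")
        p = dict(self.shape_params)
        if self.shape_kind == "sphere":
            if p.get("radius", 0) <= 0:
                raise PhantomError("sphere radius must be > 0")
        elif self.shape_kind == "torus":
            if p.get("minor_radius", 0) <= 0 or p.get("major_radius", 0) <= 0:
                raise PhantomError("torus radii must be > 0")
            if p["minor_radius"] >= p["major_radius"]:
                raise PhantomError("torus minor radius must be < major radius")
        else:
            if p.get("radius", 0) <= 0:
                raise PhantomError("tube radius must be > 0")
            if len(p.get("control_points", [])) < 2:
                raise PhantomError("tube needs >= 2 control points")
        if self.jitter is not None and len(self.jitter) != self.grid_shape[2]:
            raise PhantomError(
                f"jitter needs one transform per slice "
                f"({self.grid_shape[2]}), got {len(self.jitter)}"
            )
        for x, y, r in self.fiducials:
            if r <= 0:
                raise PhantomError("fiducial radius must be > 0")

    @property
    def center_mm(self) -> np.ndarray:
        """Physical center of the grid."""
        return np.array(
            [(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)]
        )

    def resolved_shape_params(self) -> dict:
        p = dict(self.shape_params)
        if self.shape_kind in ("sphere", "torus") and "center" not in p:
            p["center"] = tuple(self.center_mm)
        return p


# ---------------------------------------------------------------------------
# signed distance sampling
# ---------------------------------------------------------------------------


def _grid_points(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z = np.arange(nz) * dz
    return np.meshgrid(x, y, z, indexing="ij")  # each (nx, ny, nz)


def _check_extent(spec: PhantomSpec, lo: np.ndarray, hi: np.ndarray) -> None:
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing
    extent = np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz])
    for axis, name in enumerate("xyz"):
        if lo[axis] < 0 or hi[axis] > extent[axis]:
            raise PhantomError(
                f"shape exceeds grid extent along {name}: "
                f"[{lo[axis]:.3g}, {hi[axis]:.3g}] outside [0, {extent[axis]:.3g}]"
            )


def signed_distance(spec: PhantomSpec) -> np.ndarray:
    """Noise-free signed distance (negative inside), shape (nz, ny, nx)."""
    p = spec.resolved_shape_params()
    gx, gy, gz = _grid_points(spec)
    if spec.shape_kind == "sphere":
        c = np.asarray(p["center"], dtype=float)
        r = float(p["radius"])
        _check_extent(spec, c - r, c + r)
        f = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) - r
    elif spec.shape_kind == "torus":
        c = np.asarray(p["center"], dtype=float)
        major, minor = float(p["major_radius"]), float(p["minor_radius"])
        reach = np.array([major + minor, major + minor, minor])
        _check_extent(spec, c - reach, c + reach)
        rho = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2)
        f = np.sqrt((rho - major) ** 2 + (gz - c[2]) ** 2) - minor
    else:  # tube
        pts = np.asarray(p["control_points"], dtype=float)
        r = float(p["radius"])
        t = np.linspace(0.0, 1.0, len(pts))
        spline = CubicSpline(t, pts, axis=0)
        samples = spline(np.linspace(0.0, 1.0, TUBE_CENTERLINE_SAMPLES))  # (S, 3)
        _check_extent(spec, samples.min(axis=0) - r, samples.max(axis=0) + r)
        grid = np.stack([gx, gy, gz], axis=-1)  # (nx, ny, nz, 3)
        flat = grid.reshape(-1, 3)
        dmin = np.full(len(flat), np.inf)
        chunk = 65536
        for start in range(0, len(flat), chunk):
            block = flat[start : start + chunk]  # (B, 3)
            d = np.linalg.norm(block[:, None, :] - samples[None, :, :], axis=2)
            dmin[start : start + chunk] = d.min(axis=1)
        f = dmin.reshape(grid.shape[:3]) - r
    # (nx, ny, nz) -> (nz, ny, nx)
    return np.transpose(f, (2, 1, 0))


def generate_field(spec: PhantomSpec) -> Volume:
    """Sample the solid's signed-distance field at voxel centers.

    Negative inside; Gaussian noise of sd ``noise_sigma`` is added to the
    sampled values (seeded, deterministic).  The analytic ground truth is
    the spec itself (see :meth:`PhantomSpec.resolved_shape_params`).
    """
    f = signed_distance(spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sigma, size=f.shape)
    return Volume(data=f, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# slice-stack rendering
# ---------------------------------------------------------------------------


@dataclass
class StackTruth:
    """Ground truth accompanying a rendered stack.

    ``transforms[k]`` is the jitter applied to slice k (identity if none);
    ``fiducial_centers_px[k]`` are the stamped (post-jitter) disk centers in
    pixels, ``base_centers_px`` the reference-frame centers.
    """

    transforms: list[Affine2D]
    base_centers_px: np.ndarray  # (F, 2)
    fiducial_centers_px: list[np.ndarray]  # per slice (F, 2)


def silhouette_masks(spec: PhantomSpec) -> list[np.ndarray]:
    """Per-slice binary masks of the solid's silhouette (reference frame)."""
    f = signed_distance(spec)
    return [(sl < 0).astype(np.uint8) for sl in f]


def generate_slice_stack(spec: PhantomSpec) -> tuple[SliceStack, StackTruth]:
    """Render the phantom into an 8-bit grayscale slice stack.

    Each z-level of the noise-free field renders as solid interior
    (:data:`INSIDE_LEVEL`) on background, fiducial disks stamp at
    :data:`FIDUCIAL_LEVEL`, per-slice jitter (if any) is applied by bilinear
    resampling, and seeded Gaussian noise is added last.  Fiducial disks
    overlapping the solid's silhouette are an error: they would corrupt the
    registration ground truth.
    """
    f = signed_distance(spec)
    nx, ny, nz = spec.grid_shape
    dx = spec.spacing[0]
    if abs(spec.spacing[0] - spec.spacing[1]) > 1e-12:
        raise PhantomError("slice rendering requires square pixels (dx == dy)")

    base_centers = np.array([(x / dx, y / dx) for x, y, r in spec.fiducials]).reshape(-1, 2)
    fid_mask = np.zeros((ny, nx), dtype=bool)
    if spec.fiducials:
        ys, xs = np.mgrid[0:ny, 0:nx]
        for (x_mm, y_mm, r_mm) in spec.fiducials:
            cx, cy, rpx = x_mm / dx, y_mm / dx, r_mm / dx
            fid_mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= rpx**2
        silhouette_any = (f < 0).any(axis=0)
        margin = ndimage_dilate(silhouette_any)
        if (fid_mask & margin).any():
            raise PhantomError("fiducial disks overlap the solid's silhouette")

    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    transforms: list[Affine2D] = []
    stamped: list[np.ndarray] = []
    for k in range(nz):
        img = np.where(f[k] < 0, INSIDE_LEVEL, BACKGROUND_LEVEL)
        img[fid_mask] = FIDUCIAL_LEVEL
        t = spec.jitter[k] if spec.jitter is not None else Affine2D.identity()
        if not t.is_identity():
            img = resample_slice(img, t, fill_value=BACKGROUND_LEVEL)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        images.append(np.clip(img, 0.0, 255.0))
        transforms.append(t)
        stamped.append(t.apply(base_centers) if len(base_centers) else base_centers)

    stack = SliceStack(
        images=images, pixel_size=dx, slice_spacing=spec.spacing[2]
    )
    truth = StackTruth(
        transforms=transforms,
        base_centers_px=base_centers,
        fiducial_centers_px=stamped,
    )
    return stack, truth


def ndimage_dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """1-pixel 8-connected dilation (margin for the overlap check)."""
    from scipy import ndimage

    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=iterations)


def random_jitter(
    n_slices: int,
    seed: int,
    max_translation_px: float = 3.0,
    max_rotation_deg: float = 2.0,
    image_shape: tuple[int, int] | None = None,
    keep_first_identity: bool = True,
    integer_translations: bool = False,
) -> list[Affine2D]:
    """Seeded per-slice rigid jitter (rotation about the image center).

    ``integer_translations`` restricts shifts to whole pixels, under which
    bilinear resampling is exact (useful for byte-exact pipeline tests).
    """
    rng = np.random.default_rng(seed)
    center = (0.0, 0.0)
    if image_shape is not None:
        h, w = image_shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    out: list[Affine2D] = []
    for k in range(n_slices):
        if k == 0 and keep_first_identity:
            out.append(Affine2D.identity())
            continue
        t = rng.uniform(-max_translation_px, max_translation_px, size=2)
        if integer_translations:
            t = np.rint(t)
        angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
        if integer_translations:
            angle = 0.0
        out.append(Affine2D.translation(t[0], t[1]) @ Affine2D.rotation(angle, center))
    return out


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------


def write_phantom_dataset(spec: PhantomSpec, directory: str | Path) -> Path:
    """Write slices, silhouette masks, and a ground-truth JSON sidecar."""
    directory = Path(directory)
    stack, truth = generate_slice_stack(spec)
    write_stack(
        stack,
        directory,
        extra_sidecar={
            "seed": spec.seed,
            "shape_kind": spec.shape_kind,
            "shape_params": _jsonify(spec.resolved_shape_params()),
            "noise_sigma": spec.noise_sigma,
            "fiducials_mm": [list(fd) for fd in spec.fiducials],
            "jitter_matrices": [t.matrix.tolist() for t in truth.transforms],
            "fiducial_centers_px": [c.tolist() for c in truth.fiducial_centers_px],
        },
    )
    write_mask_stack(silhouette_masks(spec), directory / "masks")
    return directory


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
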