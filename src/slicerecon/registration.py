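"""Fiducial-based affine slice registration.

Each slice of a cross-sectional photograph stack may be shifted or rotated
relative to its neighbors by acquisition jitter.  Artificial landmarks
(fiducial rods, visible as disks of a distinctive gray level in every slice)
determine a 2D affine transform per slice; every slice is resampled into the frame of a
chosen reference slice.

Coordinates are pixel coordinates (x = column, y = row).  A transform T maps
reference-frame points to sensed-frame points via homogeneous 3x3 matrices
whose last row is exactly (0, 0, 1): three non-collinear fiducials determine
T exactly, more are fit by least squares.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .formats import SliceStack

logger = logging.getLogger(__name__)

#: Intensity window that isolates fiducial disks in rendered phantom slices
#: (rods render at gray level 100, solid at 255, background at 0).
DEFAULT_FIDUCIAL_WINDOW = (90.0, 110.0)

#: Connected components smaller than this many pixels are discarded as noise.
MIN_COMPONENT_PIXELS = 4


class RegistrationError(ValueError):
    """Raised for degenerate fiducial geometry or failed detection."""


@dataclass
class Affine2D:
    """A 2D affine transform in homogeneous coordinates.

    ``matrix`` is 3x3 with last row (0, 0, 1); it acts on column vectors
    (x, y, 1).  ``residual_rms`` carries the fit residual when the transform
    was estimated from point correspondences.
    """

    matrix: np.ndarray
    residual_rms: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise RegistrationError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.array_equal(m[2], [0.0, 0.0, 1.0]):
            raise RegistrationError("last row of an affine matrix must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) <= 1e-12:
            raise RegistrationError("affine transform is not invertible")
        self.matrix = m

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Affine2D":
        m = np.eye(3)
        m[0, 2], m[1, 2] = tx, ty
        return cls(m)

    @classmethod
    def rotation(cls, angle_rad: float, center: tuple[float, float] = (0.0, 0.0)) -> "Affine2D":
        """Rotation about ``center`` (pixels), counter-clockwise in (x, y)."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        cx, cy = center
        m = np.array(
            [
                [c, -s, cx - c * cx + s * cy],
                [s, c, cy - s * cx - c * cy],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(m)

    def compose(self, other: "Affine2D") -> "Affine2D":
        """self after other: (self @ other)(p) = self(other(p))."""
        return Affine2D(self.matrix @ other.matrix)

    def __matmul__(self, other: "Affine2D") -> "Affine2D":
        return self.compose(other)

    def inverse(self) -> "Affine2D":
        inv = np.linalg.inv(self.matrix)
        inv[2] = (0.0, 0.0, 1.0)  # exact, against round-off
        return Affine2D(inv)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2]

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Affine2D":
        return cls(np.array(json.loads(text)["matrix"]))


@dataclass
class FiducialSet:
    """Labeled 2D fiducial positions (x, y) in pixels, >= 3 points.

    Labels are consistent across slices: index k refers to the same physical
    rod everywhere.  Points must be pairwise separated (>= 2 px) and not
    collinear so that they determine an affine transform.
    """

    points: np.ndarray  # (N, 2)
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        n = len(self.points)
        if n < 3:
            raise RegistrationError(f"need >= 3 fiducials, got {n}")
        if not self.labels:
            self.labels = list(range(n))
        d = np.linalg.norm(self.points[:, None] - self.points[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2.0:
            raise RegistrationError(f"fiducials closer than 2 px (min {d.min():.3g})")
        if _max_triangle_area(self.points) <= 1e-6:
            raise RegistrationError("fiducials are collinear")

    def __len__(self) -> int:
        return len(self.points)


def _max_triangle_area(points: np.ndarray) -> float:
    p = points
    best = 0.0
    n = len(p)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                u, v = p[j] - p[i], p[k] - p[i]
                area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
                best = max(best, float(area))
    return best


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_fiducials(
    image: np.ndarray,
    expected_count: int = 3,
    intensity_window: tuple[float, float] = DEFAULT_FIDUCIAL_WINDOW,
) -> FiducialSet:
    """Detect fiducial disks as connected components in an intensity window.

    Pixels inside ``intensity_window`` are grouped by 8-connectivity;
    components below :data:`MIN_COMPONENT_PIXELS` are discarded; the
    ``expected_count`` largest components yield intensity-weighted centroids,
    labeled by ascending (y, x).
    """
    if expected_count < 3:
        raise RegistrationError("expected_count must be >= 3")
    img = np.asarray(image, dtype=float)
    low, high = intensity_window
    binary = (img >= low) & (img <= high)
    labels, n_found = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_found:
        sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n_found + 1))
        keep = np.flatnonzero(sizes >= MIN_COMPONENT_PIXELS) + 1
    else:
        keep = np.array([], dtype=int)
    if len(keep) < expected_count:
        raise RegistrationError(
            f"fiducial detection found {len(keep)} of {expected_count} markers"
        )
    order = keep[np.argsort(sizes[keep - 1])[::-1][:expected_count]]
    centroids = []
    struct = np.ones((3, 3), dtype=bool)
    for lab in order:
        # dilate the component so the interpolation tail of a resampled disk
        # contributes to the intensity-weighted centroid (background is dark)
        support = ndimage.binary_dilation(labels == lab, structure=struct, iterations=2)
        weights = np.where(support, img, 0.0)
        cy, cx = ndimage.center_of_mass(weights)
        centroids.append((cx, cy))
    pts = np.array(sorted(centroids, key=lambda c: (c[1], c[0])))
    return FiducialSet(points=pts)


# ---------------------------------------------------------------------------
# estimation and resampling
# ---------------------------------------------------------------------------


def estimate_affine(source: FiducialSet, target: FiducialSet) -> Affine2D:
    """Least-squares affine mapping source points onto target points.

    With exactly three non-collinear correspondences the solution
    interpolates exactly; with more, it minimizes the sum of squared
    residuals.  The RMS residual is stored on the returned transform.
    """
    if len(source) != len(target):
        raise RegistrationError(
            f"fiducial count mismatch: {len(source)} source vs {len(target)} target"
        )
    src = source.points
    tgt = target.points
    n = len(src)
    A = np.column_stack([src, np.ones(n)])  # (n, 3)
    # rows of [a b tx; c d ty] solved per output coordinate
    sol, *_ = np.linalg.lstsq(A, tgt, rcond=None)  # (3, 2)
    m = np.eye(3)
    m[:2, :] = sol.T
    residuals = A @ sol - tgt
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return Affine2D(m, residual_rms=rms)


def resample_slice(image: np.ndarray, transform: Affine2D, fill_value: float = 0.0) -> np.ndarray:
    """Bilinearly resample: output(x, y) = input(T^-1 (x, y)).

    Output dimensions equal input dimensions; samples falling outside the
    input get ``fill_value``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    inv = transform.inverse().matrix
    ys, xs = np.mgrid[0:h, 0:w]
    sx = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2]
    sy = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2]
    out = ndimage.map_coordinates(
        img, [sy.ravel(), sx.ravel()], order=1, mode="constant", cval=fill_value
    ).reshape(h, w)
    # bilinear output lies within the input range; clamp away float dust so
    # downstream inclusive threshold windows behave exactly
    lo = min(float(img.min()), fill_value)
    hi = max(float(img.max()), fill_value)
    return np.clip(out, lo, hi)


def transform_mean_displacement(
    a: Affine2D, b: Affine2D, shape: tuple[int, int], n_grid: int = 16
) -> float:
    """Mean |a(p) - b(p)| in px over a grid spanning an image of ``shape``."""
    h, w = shape
    ys, xs = np.mgrid[0 : h - 1 : n_grid * 1j, 0 : w - 1 : n_grid * 1j]
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    return float(np.mean(np.linalg.norm(a.apply(pts) - b.apply(pts), axis=1)))


def register_stack(
    stack: SliceStack,
    reference_index: int = 0,
    expected_count: int = 3,
    intensity_window: tuple[float, float] = DEFAULT_FIDUCIAL_WINDOW,
    fiducials: list[FiducialSet] | None = None,
    fill_value: float = 0.0,
) -> tuple[SliceStack, list[Affine2D]]:
    """Align every slice to the reference slice's frame.

    Fiducials are detected on every slice (or supplied explicitly); the
    affine mapping each slice's fiducials onto the reference slice's is
    estimated and applied by bilinear resampling.  Returns the registered
    stack and the per-slice transforms (identity for the reference slice).
    """
    if not 0 <= reference_index < len(stack):
        raise RegistrationError(f"reference index {reference_index} out of range")
    if fiducials is None:
        fiducials = []
        for i, img in enumerate(stack.images):
            try:
                fiducials.append(detect_fiducials(img, expected_count, intensity_window))
            except RegistrationError as exc:
                raise RegistrationError(f"slice {stack.names[i]}: {exc}") from exc
    elif len(fiducials) != len(stack):
        raise RegistrationError("one fiducial set per slice required")

    ref = fiducials[reference_index]
    transforms: list[Affine2D] = []
    images: list[np.ndarray] = []
    for i, img in enumerate(stack.images):
        if i == reference_index:
            t = Affine2D.identity()
            images.append(img.copy())
        else:
            t = estimate_affine(fiducials[i], ref)
            images.append(resample_slice(img, t, fill_value=fill_value))
            if t.residual_rms and t.residual_rms > 0.5:
                logger.warning(
                    "slice %s: fiducial fit residual %.3f px", stack.names[i], t.residual_rms
                )
        transforms.append(t)
    registered = SliceStack(
        images=images,
        pixel_size=stack.pixel_size,
        slice_spacing=stack.slice_spacing,
        names=list(stack.names),
    )
    return registered, transforms


def save_transforms(transforms: list[Affine2D], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"transforms": [t.matrix.tolist() for t in transforms]}, indent=1)
    )


def load_transforms(path: str | Path) -> list[Affine2D]:
    data = json.loads(Path(path).read_text())
    return [Affine2D(np.array(m)) for m in data["transforms"]]
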