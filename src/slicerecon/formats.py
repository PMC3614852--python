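"""Slice-stack and mesh I/O.

All other modules do file I/O through this one.  Slice stacks are read from
PNG/TIFF/JPEG images (RGB converted to ITU-R 601 luminance), meshes are
written as binary STL, Wavefront OBJ or ASCII PLY.  Writers are
deterministic: identical input produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: ITU-R 601 luma weights used for RGB -> grayscale ingestion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default in-plane pixel size in mm (cryosection photograph geometry).
DEFAULT_PIXEL_SIZE = 0.33
#: Default inter-slice distance in mm.
DEFAULT_SLICE_SPACING = 1.0

SIDECAR_NAME = "stack.json"

_LOSSY_SUFFIXES = {".jpg", ".jpeg"}


class FormatError(ValueError):
    """Raised for malformed stacks, masks or meshes."""


@dataclass
class SliceStack:
    """An ordered stack of 2D grayscale slices with physical geometry.

    ``images`` are float arrays in [0, 255], all of identical shape, ordered
    by ascending z.  ``pixel_size`` is the in-plane sample distance in mm,
    ``slice_spacing`` the distance between consecutive slices in mm.
    """

    images: list[np.ndarray]
    pixel_size: float = DEFAULT_PIXEL_SIZE
    slice_spacing: float = DEFAULT_SLICE_SPACING
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise FormatError(f"a slice stack needs >= 2 slices, got {len(self.images)}")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1 or self.images[0].ndim != 2:
            offenders = [
                (self.names[i] if i < len(self.names) else f"slice {i}", im.shape)
                for i, im in enumerate(self.images)
                if im.shape != self.images[0].shape or im.ndim != 2
            ]
            raise FormatError(f"slices have mixed dimensions: {offenders}")
        if not (self.pixel_size > 0 and self.slice_spacing > 0):
            raise FormatError(
                f"pixel_size and slice_spacing must be > 0, got "
                f"{self.pixel_size}, {self.slice_spacing}"
            )
        if not self.names:
            self.names = [f"slice_{i:04d}" for i in range(len(self.images))]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every slice."""
        return self.images[0].shape

    def as_array(self) -> np.ndarray:
        """Stack as a (nz, ny, nx) float array."""
        return np.stack(self.images, axis=0)


@dataclass
class IsoSurfaceMesh:
    """A triangle mesh: vertex positions in mm and optional unit normals."""

    vertices: np.ndarray  # (N, 3) float
    triangles: np.ndarray  # (M, 3) int
    normals: np.ndarray | None = None  # (N, 3) float, unit length

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)

    def validate(self) -> None:
        n = len(self.vertices)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise FormatError("triangle index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise FormatError("triangle repeats a vertex index")
        if self.normals is not None:
            if self.normals.shape != self.vertices.shape:
                raise FormatError("normals shape must match vertices")
            norms = np.linalg.norm(self.normals, axis=1)
            if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
                raise FormatError("normals must be unit length to 1e-6")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


# ---------------------------------------------------------------------------
# stack reading / writing
# ---------------------------------------------------------------------------


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs as integers (slice_2 before slice_10)."""
    parts = re.split(r"(\d+)", Path(name).name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Convert an image array to float luminance in [0, 255]."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        r, g, b = LUMA_WEIGHTS
        return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]
    raise FormatError(f"unsupported image shape {img.shape}")


def _collect_files(source: str | Path | Sequence[str | Path]) -> list[Path]:
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        files = [
            p
            for p in Path(source).iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
        ]
    else:
        files = [Path(p) for p in source]  # type: ignore[union-attr]
    return sorted(files, key=lambda p: _natural_key(p.name))


def read_stack(
    source: str | Path | Sequence[str | Path],
    pixel_size: float | None = None,
    slice_spacing: float | None = None,
) -> SliceStack:
    """Read an ordered slice stack from a directory or explicit file list.

    Files are ordered by natural filename sort.  A ``stack.json`` sidecar in
    the directory supplies spacing metadata unless overridden by the
    ``pixel_size`` / ``slice_spacing`` arguments.
    """
    sidecar: dict = {}
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        sc = Path(source) / SIDECAR_NAME
        if sc.exists():
            sidecar = json.loads(sc.read_text())
    files = _collect_files(source)
    if len(files) < 2:
        raise FormatError(f"a slice stack needs >= 2 slices, found {len(files)}")
    images = [to_luminance(iio.imread(f)) for f in files]
    return SliceStack(
        images=images,
        pixel_size=pixel_size or sidecar.get("pixel_size_mm", DEFAULT_PIXEL_SIZE),
        slice_spacing=slice_spacing or sidecar.get("slice_spacing_mm", DEFAULT_SLICE_SPACING),
        names=[f.name for f in files],
    )


def write_stack(stack: SliceStack, directory: str | Path, extra_sidecar: dict | None = None) -> list[Path]:
    """Write a stack as zero-padded numbered 8-bit PNGs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(stack.images):
        p = directory / f"slice_{i:04d}.png"
        iio.imwrite(p, np.clip(np.rint(img), 0, 255).astype(np.uint8))
        paths.append(p)
    sidecar = {
        "pixel_size_mm": stack.pixel_size,
        "slice_spacing_mm": stack.slice_spacing,
        "n_slices": len(stack),
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# mask reading / writing
# ---------------------------------------------------------------------------


def binarize_mask(image: np.ndarray, lossy: bool = False) -> np.ndarray:
    """Ingest a mask image as a {0, 1} uint8 array.

    Lossless sources binarize any nonzero pixel to 1; lossy (JPEG) sources,
    whose compression introduces ringing, binarize at >= 128.
    """
    img = to_luminance(image)
    if lossy:
        return (img >= 128).astype(np.uint8)
    return (img != 0).astype(np.uint8)


def read_mask_stack(
    source: str | Path | Sequence[str | Path],
    companion: SliceStack | None = None,
) -> list[np.ndarray]:
    """Read a stack of binary masks; optionally check against a companion stack."""
    files = _collect_files(source)
    if not files:
        raise FormatError("no mask images found")
    masks = [
        binarize_mask(iio.imread(f), lossy=f.suffix.lower() in _LOSSY_SUFFIXES)
        for f in files
    ]
    if companion is not None:
        if len(masks) != len(companion):
            raise FormatError(
                f"mask count {len(masks)} does not match stack count {len(companion)}"
            )
        for i, (m, im) in enumerate(zip(masks, companion.images)):
            if m.shape != im.shape:
                raise FormatError(
                    f"mask {files[i].name} shape {m.shape} mismatches slice shape {im.shape}"
                )
    return masks


def write_mask_stack(masks: Iterable[np.ndarray], directory: str | Path) -> list[Path]:
    """Write binary masks as 0/255 PNG files (lossless by design)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(masks):
        m = np.asarray(m)
        p = directory / f"mask_{i:04d}.png"
        iio.imwrite(p, ((m != 0) * 255).astype(np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# mesh writing / reading
# ---------------------------------------------------------------------------

_STL_HEADER = b"slicerecon binary STL" + b" " * 59  # fixed 80 bytes, no timestamp


def _facet_normals(mesh: IsoSurfaceMesh) -> np.ndarray:
    v = mesh.vertices
    t = mesh.triangles
    if not len(t):
        return np.zeros((0, 3))
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    lengths = np.linalg.norm(n, axis=1)
    ok = lengths > 0
    n[ok] /= lengths[ok, None]
    n[~ok] = 0.0
    return n


def write_mesh(mesh: IsoSurfaceMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh as binary STL, OBJ or ASCII PLY (inferred from suffix).

    An empty mesh writes a valid zero-triangle file (with a logged warning).
    """
    mesh.validate()
    path = Path(path)
    if fmt is None:
        fmt = {".stl": "stl_binary", ".obj": "obj", ".ply": "ply_ascii"}.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer mesh format from suffix {path.suffix!r}")
    if mesh.n_triangles == 0:
        logger.warning("writing empty mesh to %s", path)
    if fmt == "stl_binary":
        _write_stl(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply_ascii":
        _write_ply(mesh, path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")
    return path


def _write_stl(mesh: IsoSurfaceMesh, path: Path) -> None:
    v32 = mesh.vertices.astype("<f4")
    normals = _facet_normals(mesh).astype("<f4")
    with open(path, "wb") as fh:
        fh.write(_STL_HEADER)
        fh.write(struct.pack("<I", mesh.n_triangles))
        for k, tri in enumerate(mesh.triangles):
            fh.write(normals[k].tobytes())
            for idx in tri:
                fh.write(v32[idx].tobytes())
            fh.write(b"\x00\x00")


def _fmt_float(x: float) -> str:
    return format(x, ".9g")


def _write_obj(mesh: IsoSurfaceMesh, path: Path) -> None:
    lines = ["# slicerecon OBJ"]
    for p in mesh.vertices:
        lines.append(f"v {_fmt_float(p[0])} {_fmt_float(p[1])} {_fmt_float(p[2])}")
    has_n = mesh.normals is not None
    if has_n:
        for n in mesh.normals:
            lines.append(f"vn {_fmt_float(n[0])} {_fmt_float(n[1])} {_fmt_float(n[2])}")
    for t in mesh.triangles:
        a, b, c = (int(i) + 1 for i in t)
        if has_n:
            lines.append(f"f {a}//{a} {b}//{b} {c}//{c}")
        else:
            lines.append(f"f {a} {b} {c}")
    path.write_text("\n".join(lines) + "\n")


def _write_ply(mesh: IsoSurfaceMesh, path: Path) -> None:
    has_n = mesh.normals is not None
    header = [
        "ply",
        "format ascii 1.0",
        "comment slicerecon",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if has_n:
        header += ["property float nx", "property float ny", "property float nz"]
    header += [
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines = header
    for i, p in enumerate(mesh.vertices):
        row = [_fmt_float(p[0]), _fmt_float(p[1]), _fmt_float(p[2])]
        if has_n:
            row += [_fmt_float(mesh.normals[i][j]) for j in range(3)]
        lines.append(" ".join(row))
    for t in mesh.triangles:
        lines.append(f"3 {int(t[0])} {int(t[1])} {int(t[2])}")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> IsoSurfaceMesh:
    """Read back a mesh written by :func:`write_mesh`.

    STL stores unwelded triangle soup; bitwise-identical vertex positions are
    re-welded on read so connectivity (and metrics like watertightness)
    survive a round trip.  OBJ and PLY preserve vertex sharing and normals.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        return _read_stl(path)
    if suffix == ".obj":
        return _read_obj(path)
    if suffix == ".ply":
        return _read_ply(path)
    raise FormatError(f"unknown mesh suffix {path.suffix!r}")


def _read_stl(path: Path) -> IsoSurfaceMesh:
    raw = path.read_bytes()
    (count,) = struct.unpack_from("<I", raw, 80)
    vertices = np.zeros((3 * count, 3))
    triangles = np.arange(3 * count, dtype=np.int64).reshape(-1, 3)
    off = 84
    for k in range(count):
        rec = np.frombuffer(raw, dtype="<f4", count=12, offset=off)
        vertices[3 * k : 3 * k + 3] = rec[3:].reshape(3, 3)
        off += 50
    if count:
        uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
        vertices, triangles = uniq, inverse[triangles]
    return IsoSurfaceMesh(vertices=vertices, triangles=triangles)


def _read_obj(path: Path) -> IsoSurfaceMesh:
    verts, norms, tris = [], [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "vn":
            norms.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            tris.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return IsoSurfaceMesh(
        vertices=np.array(verts).reshape(-1, 3),
        triangles=np.array(tris, dtype=np.int64).reshape(-1, 3),
        normals=np.array(norms) if norms else None,
    )


def _read_ply(path: Path) -> IsoSurfaceMesh:
    lines = path.read_text().splitlines()
    n_vert = n_face = 0
    props: list[str] = []
    i = 0
    element = None
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vert = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "vertex" and parts[1] == "float":
            props.append(parts[2])
        elif parts[0] == "end_header":
            break
    body = lines[i + 1 :]
    vdata = np.array([[float(x) for x in body[k].split()] for k in range(n_vert)])
    verts = vdata[:, :3] if n_vert else np.zeros((0, 3))
    normals = None
    if "nx" in props and n_vert:
        j = props.index("nx")
        normals = vdata[:, j : j + 3]
    tris = [
        [int(x) for x in body[n_vert + k].split()[1:4]] for k in range(n_face)
    ]
    return IsoSurfaceMesh(
        vertices=verts,
        triangles=np.array(tris, dtype=np.int64).reshape(-1, 3),
        normals=normals,
    )
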