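"""Marching-cubes kernel.

Each cube of 8 neighboring volume samples is classified into one of 256
corner-sign configurations (corner state S_i = 1 iff q_i >= isovalue, with
the boundary counting as inside).  A 256-entry case table maps the
configuration index to a triangle tessellation over the cube's 12 edges;
surface vertices are placed on intersected edges by linear interpolation,
welded across neighboring cubes, and given gradient normals from central
differences of the volume.

Conventions (fixed for this package):

* Corner ``i`` occupies offset ``((i>>0)&1, (i>>1)&1, (i>>2)&1)`` along
  (x, y, z); the configuration index is ``sum(S_i << i)``.
* Edges 0-3 run along x, 4-7 along y, 8-11 along z:

  ====  ============  ====  ============  ====  ============
  edge  corners       edge  corners       edge  corners
  ====  ============  ====  ============  ====  ============
  0     0-1           4     0-2           8     0-4
  1     2-3           5     1-3           9     1-5
  2     4-5           6     4-6           10    2-6
  3     6-7           7     5-7           11    3-7
  ====  ============  ====  ============  ====  ============

* Triangle winding: emitted normals point from the high-valued (S=1) side
  toward the low side, so solids rendered bright-inside get outward normals.

The 256-entry table is expanded from 15 base-case tessellations (one per
equivalence class of configurations under the 24 proper cube rotations
combined with complementation) by applying the rotations; complementary
configurations reuse the intersected-edge set with reversed winding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .formats import IsoSurfaceMesh
from .volume import Volume

logger = logging.getLogger(__name__)


class MarchingCubesError(ValueError):
    """Raised for invalid kernel inputs or internal table inconsistency."""


#: Corner index -> (x, y, z) offset within the cube.
CORNER_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    ((i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1) for i in range(8)
)

#: Edge index -> (corner, corner); the first corner is the lower one.
EDGE_CORNERS: tuple[tuple[int, int], ...] = (
    (0, 1), (2, 3), (4, 5), (6, 7),   # x-aligned
    (0, 2), (1, 3), (4, 6), (5, 7),   # y-aligned
    (0, 4), (1, 5), (2, 6), (3, 7),   # z-aligned
)

_EDGE_INDEX = {frozenset(pair): i for i, pair in enumerate(EDGE_CORNERS)}

#: Axis (0=x, 1=y, 2=z) along which each edge runs.
EDGE_AXIS: tuple[int, ...] = tuple(i // 4 for i in range(12))

#: Base-case tessellations, one per symmetry class representative.
#: Derived once by a face-consistent cycle construction (per cube face,
#: marching-squares segments with ambiguous faces resolved by separating the
#: high corners; cut edges chained into cycles and fan-triangulated, oriented
#: so normals point from the high side to the low side) and frozen here.
BASE_CASES: dict[int, tuple[tuple[int, int, int], ...]] = {
    0: (),
    1: ((0, 4, 8),),
    3: ((4, 8, 9), (4, 9, 5)),
    6: ((0, 9, 5), (1, 10, 4)),
    7: ((1, 10, 8), (1, 8, 9), (1, 9, 5)),
    15: ((8, 11, 10), (8, 9, 11)),
    22: ((0, 9, 5), (1, 10, 4), (2, 8, 6)),
    23: ((1, 10, 6), (1, 6, 2), (1, 2, 9), (1, 9, 5)),
    24: ((1, 5, 11), (2, 8, 6)),
    25: ((0, 6, 2), (0, 4, 6), (1, 5, 11)),
    27: ((1, 9, 11), (1, 2, 9), (1, 6, 2), (1, 4, 6)),
    29: ((0, 6, 2), (0, 10, 6), (0, 11, 10), (0, 5, 11)),
    30: ((0, 9, 11), (0, 11, 10), (0, 10, 4), (2, 8, 6)),
    60: ((4, 11, 10), (4, 5, 11), (6, 9, 8), (6, 7, 9)),
    105: ((0, 4, 8), (1, 5, 11), (2, 7, 9), (3, 6, 10)),
}


@dataclass(frozen=True)
class CornerConfiguration:
    """The 8 corner states of one cube against an isovalue."""

    corner_values: tuple[float, ...]
    isovalue: float
    states: tuple[int, ...]
    index: int


def classify_corners(corner_values, isovalue: float) -> CornerConfiguration:
    """Classify 8 corner samples: state 1 iff value >= isovalue.

    The boundary (value equal to the isovalue) counts as inside; the index
    is ``sum(S_i << i)`` in 0..255.
    """
    vals = tuple(float(v) for v in np.asarray(corner_values).ravel())
    if len(vals) != 8:
        raise MarchingCubesError(f"need 8 corner values, got {len(vals)}")
    if not all(np.isfinite(vals)) or not np.isfinite(isovalue):
        raise MarchingCubesError("corner values and isovalue must be finite")
    states = tuple(1 if q >= isovalue else 0 for q in vals)
    index = sum(s << i for i, s in enumerate(states))
    return CornerConfiguration(vals, float(isovalue), states, index)


# ---------------------------------------------------------------------------
# symmetry machinery and table construction
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def rotation_permutations() -> tuple[tuple[int, ...], ...]:
    """The 24 proper rotations of the cube as corner permutations."""
    perms: list[tuple[int, ...]] = []
    seen = set()
    for axes in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            rot = np.zeros((3, 3))
            for r, (a, s) in enumerate(zip(axes, signs)):
                rot[r, a] = s
            if round(float(np.linalg.det(rot))) != 1:
                continue
            perm = []
            for i in range(8):
                v = np.array(CORNER_OFFSETS[i], dtype=float) - 0.5
                w = rot @ v + 0.5
                perm.append(
                    int(round(w[0])) | (int(round(w[1])) << 1) | (int(round(w[2])) << 2)
                )
            t = tuple(perm)
            if t not in seen:
                seen.add(t)
                perms.append(t)
    if len(perms) != 24:  # pragma: no cover - structural guarantee
        raise MarchingCubesError(f"expected 24 rotations, built {len(perms)}")
    return tuple(perms)


def permute_index(index: int, perm: tuple[int, ...]) -> int:
    """Apply a corner permutation to a configuration index."""
    out = 0
    for i in range(8):
        if index >> i & 1:
            out |= 1 << perm[i]
    return out


def _edge_permutation(perm: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(
        _EDGE_INDEX[frozenset((perm[a], perm[b]))] for a, b in EDGE_CORNERS
    )


def symmetry_classes() -> list[list[int]]:
    """Brute-force orbits of the 256 configurations under rotations x complement."""
    seen = [False] * 256
    orbits: list[list[int]] = []
    for i in range(256):
        if seen[i]:
            continue
        orbit = set()
        for perm in rotation_permutations():
            j = permute_index(i, perm)
            orbit.add(j)
            orbit.add(255 - j)
        for j in orbit:
            seen[j] = True
        orbits.append(sorted(orbit))
    return orbits


def count_symmetry_classes() -> int:
    """Number of unique cases under rotations combined with complementation."""
    return len(symmetry_classes())


def count_nonempty_configurations() -> int:
    """Enumerate all 2^8 binary corner patterns; count those with any corner set.

    Runs every pattern through :func:`classify_corners` and counts nonzero
    configuration indices.
    """
    count = 0
    for bits in range(256):
        vals = [1.0 if bits >> i & 1 else 0.0 for i in range(8)]
        if classify_corners(vals, 0.5).index != 0:
            count += 1
    return count


@dataclass(frozen=True)
class CaseTable:
    """256-entry map from configuration index to triangles of edge indices."""

    entries: tuple[tuple[tuple[int, int, int], ...], ...]

    def __getitem__(self, index: int) -> tuple[tuple[int, int, int], ...]:
        return self.entries[index]

    def to_json_dict(self) -> dict:
        return {str(i): [list(t) for t in e] for i, e in enumerate(self.entries)}


@lru_cache(maxsize=1)
def build_case_table() -> CaseTable:
    """Expand the 15 base cases into the full 256-entry table.

    Every configuration index reachable from a base case by a proper rotation
    gets the rotated tessellation; the complementary index gets the same
    intersected-edge set with reversed winding.  Construction is
    deterministic; an unassigned index indicates a broken base case.
    """
    entries: list[tuple[tuple[int, int, int], ...] | None] = [None] * 256
    for rep in sorted(BASE_CASES):
        tris = BASE_CASES[rep]
        for perm in rotation_permutations():
            idx = permute_index(rep, perm)
            eperm = _edge_permutation(perm)
            mapped = tuple((eperm[a], eperm[b], eperm[c]) for a, b, c in tris)
            if entries[idx] is None:
                entries[idx] = mapped
            comp = 255 - idx
            if entries[comp] is None:
                entries[comp] = tuple((c, b, a) for a, b, c in mapped)
    for idx, entry in enumerate(entries):
        if entry is None:
            raise MarchingCubesError(f"case table construction left index {idx} unassigned")
        for tri in entry:
            for e in tri:
                a, b = EDGE_CORNERS[e]
                if (idx >> a & 1) == (idx >> b & 1):
                    raise MarchingCubesError(
                        f"entry {idx} references edge {e} joining same-state corners"
                    )
        if idx in (0, 255) and entry:
            raise MarchingCubesError("empty configurations must have empty entries")
        if idx not in (0, 255) and not entry:
            raise MarchingCubesError(f"non-trivial configuration {idx} has no triangles")
    return CaseTable(entries=tuple(entries))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# edge interpolation and gradients
# ---------------------------------------------------------------------------


def interpolate_edge(p_i, q_i: float, p_j, q_j: float, isovalue: float):
    """Linear iso-point on the segment p_i..p_j.

    Returns (Q, position) with Q = (C0 - q_i) / (q_j - q_i) in [0, 1] and
    position = p_i + Q (p_j - p_i).
    """
    if q_i == q_j:
        raise MarchingCubesError("edge endpoints share a value; corner states cannot differ")
    q = (isovalue - q_i) / (q_j - q_i)
    if not -1e-12 <= q <= 1 + 1e-12:
        raise MarchingCubesError(f"interpolation parameter {q} outside [0, 1]")
    q = min(max(q, 0.0), 1.0)
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    return q, p_i + q * (p_j - p_i)


def gradient_field(volume: Volume) -> np.ndarray:
    """Per-sample gradient (gx, gy, gz) by central differences.

    Interior samples use (D[i+1] - D[i-1]) / delta along each axis (no
    conventional factor 1/2; normals are normalized downstream so the scale
    cancels); boundary samples fall back to one-sided differences.
    """
    d = volume.data  # (z, y, x)
    dx, dy, dz = volume.spacing
    out = np.empty(d.shape + (3,))
    for comp, (axis, delta) in enumerate(((2, dx), (1, dy), (0, dz))):
        g = np.empty_like(d)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        mid = [slice(None)] * 3
        lo[axis], hi[axis], mid[axis] = slice(0, -2), slice(2, None), slice(1, -1)
        g[tuple(mid)] = (d[tuple(hi)] - d[tuple(lo)]) / delta
        first_hi = [slice(None)] * 3
        first_lo = [slice(None)] * 3
        first_hi[axis], first_lo[axis] = slice(1, 2), slice(0, 1)
        g[tuple(first_lo)] = (d[tuple(first_hi)] - d[tuple(first_lo)]) / delta
        last_hi = [slice(None)] * 3
        last_lo = [slice(None)] * 3
        last_hi[axis], last_lo[axis] = slice(-1, None), slice(-2, -1)
        g[tuple(last_hi)] = (d[tuple(last_hi)] - d[tuple(last_lo)]) / delta
        out[..., comp] = g
    return out


def vertex_gradient(volume: Volume, grid_position: tuple[int, int, int]) -> np.ndarray:
    """Gradient at an integer grid position (ix, iy, iz).

    Strictly interior samples use central differences; boundary samples
    substitute one-sided differences (logged at debug level).
    """
    ix, iy, iz = grid_position
    nz, ny, nx = volume.data.shape
    if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
        raise MarchingCubesError(f"grid position {grid_position} outside volume")
    if not (1 <= ix <= nx - 2 and 1 <= iy <= ny - 2 and 1 <= iz <= nz - 2):
        logger.debug("one-sided gradient at boundary sample %s", grid_position)
    return gradient_field(volume)[iz, iy, ix]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_isosurface(
    volume: Volume, isovalue: float, pad: bool = True
) -> IsoSurfaceMesh:
    """March every cube of the volume and assemble the isosurface mesh.

    Vertices on shared cube edges are welded by exact (grid edge) identity;
    per-vertex normals come from gradient interpolation along the intersected
    edge, normalized and negated so they point from high values to low.  If
    the isovalue touches the outer boundary layer the surface would be
    clipped: with ``pad=True`` (default) a one-sample layer below the
    isovalue is added, otherwise a warning is logged.
    """
    if not np.isfinite(isovalue):
        raise MarchingCubesError("isovalue must be finite")
    data = volume.data
    origin = np.asarray(volume.origin, dtype=float)
    spacing = np.asarray(volume.spacing, dtype=float)

    boundary_hot = bool(
        (data[0] >= isovalue).any()
        or (data[-1] >= isovalue).any()
        or (data[:, 0] >= isovalue).any()
        or (data[:, -1] >= isovalue).any()
        or (data[:, :, 0] >= isovalue).any()
        or (data[:, :, -1] >= isovalue).any()
    )
    if boundary_hot:
        if pad:
            pad_value = min(float(data.min()), isovalue) - max(1.0, abs(isovalue) * 1e-3)
            data = np.pad(data, 1, constant_values=pad_value)
            origin = origin - spacing
            logger.info("isovalue touches volume boundary; auto-padded one layer")
        else:
            logger.warning(
                "isovalue touches volume boundary; surface will be clipped "
                "(consider zero-padding)"
            )

    table = build_case_table()
    s = data >= isovalue
    nz, ny, nx = data.shape
    index = np.zeros((nz - 1, ny - 1, nx - 1), dtype=np.uint16)
    for i, (ox, oy, oz) in enumerate(CORNER_OFFSETS):
        index |= s[oz : oz + nz - 1, oy : oy + ny - 1, ox : ox + nx - 1].astype(np.uint16) << i
    active = np.argwhere((index > 0) & (index < 255))

    grad = gradient_field(
        Volume(data, tuple(spacing), tuple(origin)) if boundary_hot and pad else volume
    )

    vertex_ids: dict[tuple[int, int, int, int], int] = {}
    positions: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    needs_fallback: list[int] = []
    triangles: list[tuple[int, int, int]] = []
    axis_unit = np.eye(3)

    def vertex_on_edge(cz: int, cy: int, cx: int, e: int) -> int:
        a, _b = EDGE_CORNERS[e]
        axis = EDGE_AXIS[e]
        ox, oy, oz = CORNER_OFFSETS[a]
        gx, gy, gz = cx + ox, cy + oy, cz + oz
        key = (axis, gx, gy, gz)
        vid = vertex_ids.get(key)
        if vid is not None:
            return vid
        qa = data[gz, gy, gx]
        step = [0, 0, 0]
        step[axis] = 1
        qb = data[gz + step[2], gy + step[1], gx + step[0]]
        q, _ = interpolate_edge((0.0, 0.0, 0.0), qa, tuple(axis_unit[axis]), qb, isovalue)
        pos = origin + (np.array([gx, gy, gz]) + q * axis_unit[axis]) * spacing
        ga = grad[gz, gy, gx]
        gb = grad[gz + step[2], gy + step[1], gx + step[0]]
        g = (1.0 - q) * ga + q * gb
        norm = np.linalg.norm(g)
        vid = len(positions)
        positions.append(pos)
        if norm > 1e-12:
            normals.append(-g / norm)
        else:
            normals.append(np.zeros(3))
            needs_fallback.append(vid)
        vertex_ids[key] = vid
        return vid

    for cz, cy, cx in active:
        for tri in table[int(index[cz, cy, cx])]:
            vids = (
                vertex_on_edge(cz, cy, cx, tri[0]),
                vertex_on_edge(cz, cy, cx, tri[1]),
                vertex_on_edge(cz, cy, cx, tri[2]),
            )
            triangles.append(vids)

    if not triangles:
        return IsoSurfaceMesh(
            vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=np.int64),
            normals=np.zeros((0, 3)),
        )

    verts = np.array(positions)
    tris = np.array(triangles, dtype=np.int64)
    norms = np.array(normals)

    # When Q hits exactly 0 or 1 (a sample equal to the isovalue) the
    # iso-point lands on a grid sample shared by several edges; the
    # (cube, edge) welding cannot identify those, so merge bitwise-identical
    # positions (tolerance-free) and then drop the collapsed triangles.
    uniq, first_idx, inverse = np.unique(
        verts, axis=0, return_index=True, return_inverse=True
    )
    if len(uniq) < len(verts):
        verts = uniq
        norms = norms[first_idx]
        needs_fallback = sorted({int(inverse[v]) for v in needs_fallback})
        tris = inverse[tris]
    degenerate = (
        (tris[:, 0] == tris[:, 1]) | (tris[:, 1] == tris[:, 2]) | (tris[:, 0] == tris[:, 2])
    )
    if degenerate.any():
        logger.info("dropped %d degenerate zero-area triangles", int(degenerate.sum()))
        tris = tris[~degenerate]

    if needs_fallback:
        geom = np.cross(
            verts[tris[:, 1]] - verts[tris[:, 0]], verts[tris[:, 2]] - verts[tris[:, 0]]
        )
        acc = np.zeros_like(verts)
        for k in range(3):
            np.add.at(acc, tris[:, k], geom)
        for vid in needs_fallback:
            n = acc[vid]
            length = np.linalg.norm(n)
            normal = n / length if length > 1e-12 else np.array([0.0, 0.0, 1.0])
            norms[vid] = normal

    return IsoSurfaceMesh(vertices=verts, triangles=tris, normals=norms)
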