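"""Mesh validation and quality metrics.

Reconstructed surfaces should be closed ("watertight"): every undirected
edge bordered by exactly two triangles.  Closed, consistently wound meshes
admit an enclosed volume via the divergence theorem (sum of signed
tetrahedra against the origin); the Euler characteristic V - E + F checks
the topology (2 for a sphere-like surface, 0 for a torus).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np

from .formats import IsoSurfaceMesh

logger = logging.getLogger(__name__)


class MeshError(ValueError):
    """Raised when a metric's preconditions fail."""


@dataclass(frozen=True)
class WatertightReport:
    is_closed: bool
    boundary_edge_count: int
    non_manifold_edge_count: int

    def as_dict(self) -> dict:
        return asdict(self)


def _edge_census(mesh: IsoSurfaceMesh) -> Counter:
    census: Counter = Counter()
    for a, b, c in mesh.triangles:
        for u, v in ((a, b), (b, c), (c, a)):
            census[(min(u, v), max(u, v))] += 1
    return census


def watertight_check(mesh: IsoSurfaceMesh) -> WatertightReport:
    """Census undirected edges; closed iff every edge has incidence 2."""
    census = _edge_census(mesh)
    boundary = sum(1 for n in census.values() if n == 1)
    non_manifold = sum(1 for n in census.values() if n > 2)
    is_closed = bool(census) and boundary == 0 and non_manifold == 0
    return WatertightReport(is_closed, boundary, non_manifold)


def euler_characteristic(mesh: IsoSurfaceMesh) -> int:
    """V - E + F over referenced vertices and undirected edges."""
    if not len(mesh.triangles):
        return 0
    v = len(np.unique(mesh.triangles))
    e = len(_edge_census(mesh))
    f = len(mesh.triangles)
    return v - e + f


def surface_area(mesh: IsoSurfaceMesh) -> float:
    """Total triangle area in mm^2 (invariant to winding)."""
    verts = mesh.vertices
    t = mesh.triangles
    if not len(t):
        return 0.0
    n = np.cross(verts[t[:, 1]] - verts[t[:, 0]], verts[t[:, 2]] - verts[t[:, 0]])
    return float(np.linalg.norm(n, axis=1).sum() / 2.0)


def enclosed_volume(mesh: IsoSurfaceMesh) -> float:
    """Enclosed volume in mm^3 of a watertight mesh.

    Sums signed tetrahedron volumes v0 . (v1 x v2) / 6 against the origin;
    the absolute value makes the result winding-independent (a flipped
    orientation is logged).  Raises on a non-watertight mesh.
    """
    report = watertight_check(mesh)
    if not report.is_closed:
        raise MeshError(
            "enclosed_volume requires a watertight mesh: "
            f"{report.boundary_edge_count} boundary, "
            f"{report.non_manifold_edge_count} non-manifold edges"
        )
    verts = mesh.vertices
    t = mesh.triangles
    signed = np.einsum(
        "ij,ij->i", verts[t[:, 0]], np.cross(verts[t[:, 1]], verts[t[:, 2]])
    ).sum() / 6.0
    if signed < 0:
        logger.info("mesh winding is inward; reporting |volume|")
    return float(abs(signed))


def mesh_report(mesh: IsoSurfaceMesh) -> dict:
    """Full metric report as a JSON-ready dict."""
    wt = watertight_check(mesh)
    report = {
        "n_vertices": int(mesh.n_vertices),
        "n_triangles": int(mesh.n_triangles),
        "watertight": wt.as_dict(),
        "euler_characteristic": euler_characteristic(mesh),
        "surface_area_mm2": surface_area(mesh),
    }
    report["enclosed_volume_mm3"] = enclosed_volume(mesh) if wt.is_closed else None
    return report
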