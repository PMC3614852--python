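"""Inspect the marching-cubes machinery directly.

Counts the corner-sign configurations and their symmetry classes, classifies
one cube against an isovalue, interpolates an edge iso-point, and extracts
the octahedron around a single hot sample.
"""

import numpy as np

import slicerecon as sr

print("non-empty corner configurations:", sr.count_nonempty_configurations())
print("unique cases under rotations x complementation:",
      sr.count_symmetry_classes())

table = sr.build_case_table()
print("single-corner case 1 tessellation (edge indices):", table[1])

cfg = sr.classify_corners([0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1], isovalue=0.5)
print(f"corner states {cfg.states} -> index {cfg.index}")

q, pos = sr.interpolate_edge((0, 0, 0), 0.2, (0, 0, 2), 0.8, isovalue=0.5)
print(f"edge iso-point at Q={q}: {pos}")

data = np.zeros((5, 5, 5))
data[2, 2, 2] = 1.0
mesh = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=False)
print(f"one hot sample -> {mesh.n_vertices} vertices, {mesh.n_triangles} "
      f"triangles, euler {sr.euler_characteristic(mesh)} (octahedron)")
# 255 of the 256 configurations intersect the surface; symmetry reduces them
# to 15 unique tessellation cases, from which the full table is expanded.
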