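"""Marching-cubes kernel: classification, case table, interpolation, normals,
extraction topology and geometry."""

import numpy as np
import pytest

import slicerecon as sr
from slicerecon import mc_core
from slicerecon.mc_core import (
    EDGE_CORNERS,
    MarchingCubesError,
    build_case_table,
    permute_index,
    rotation_permutations,
)

from conftest import bright_field


class TestClassify:
    @pytest.mark.parametrize(
        "values,iso,index",
        [
            ([0.0] * 8, 0.5, 0),
            ([1.0] * 8, 0.5, 255),
            ([0.5] + [0.0] * 7, 0.5, 1),  # boundary counts as inside (>= rule)
        ],
    )
    def test_state_rule(self, values, iso, index):
        cfg = sr.classify_corners(values, iso)
        assert cfg.index == index

    def test_nonfinite_rejected(self):
        with pytest.raises(MarchingCubesError, match="finite"):
            sr.classify_corners([np.nan] + [0.0] * 7, 0.5)

    def test_nonempty_configuration_count(self):
        assert sr.count_nonempty_configurations() == 255


class TestCaseTable:
    def test_fifteen_symmetry_classes(self):
        orbits = mc_core.symmetry_classes()
        assert len(orbits) == 15
        assert sorted(sum((o for o in orbits), [])) == list(range(256))

    def test_trivial_entries_empty_others_not(self):
        table = build_case_table()
        assert table[0] == () and table[255] == ()
        assert all(len(table[i]) >= 1 for i in range(1, 255))

    def test_single_corner_cases_are_one_triangle(self):
        table = build_case_table()
        for bit in range(8):
            assert len(table[1 << bit]) == 1

    def test_every_referenced_edge_is_cut(self):
        table = build_case_table()
        for idx in range(256):
            for tri in table[idx]:
                for e in tri:
                    a, b = EDGE_CORNERS[e]
                    assert (idx >> a & 1) != (idx >> b & 1)

    def test_complement_entries_reverse_winding(self):
        table = build_case_table()
        for idx in (1, 9, 65, 130):
            fwd = {frozenset(t) for t in table[idx]}
            rev = {frozenset(t) for t in table[255 - idx]}
            assert fwd == rev

    def test_rotations_form_group_of_24(self):
        perms = rotation_permutations()
        assert len(set(perms)) == 24
        closed = {tuple(p[q[i]] for i in range(8)) for p in perms for q in perms}
        assert closed == set(perms)
        assert permute_index(0b1, perms[0]) in {1 << b for b in range(8)}


class TestInterpolateEdge:
    @pytest.mark.parametrize(
        "qi,qj,iso,pi,pj,expected_q,expected_pos",
        [
            (0.5, 0.0, 0.5, (1, 2, 3), (4, 5, 6), 0.0, (1, 2, 3)),
            (0.0, 1.0, 0.5, (0, 0, 0), (1, 0, 0), 0.5, (0.5, 0, 0)),
            (0.2, 0.8, 0.5, (0, 0, 0), (0, 0, 2), 0.5, (0, 0, 1.0)),
        ],
    )
    def test_linear_isopoint(self, qi, qj, iso, pi, pj, expected_q, expected_pos):
        q, pos = sr.interpolate_edge(pi, qi, pj, qj, iso)
        assert q == pytest.approx(expected_q)
        assert np.allclose(pos, expected_pos)

    def test_equal_values_rejected(self):
        with pytest.raises(MarchingCubesError, match="share a value"):
            sr.interpolate_edge((0, 0, 0), 1.0, (1, 0, 0), 1.0, 1.0)


class TestGradients:
    def test_constant_volume_gives_zero_and_geometric_fallback(self):
        vol = sr.Volume(np.zeros((5, 5, 5)), (1, 1, 1))
        assert np.array_equal(sr.vertex_gradient(vol, (2, 2, 2)), np.zeros(3))
        # one hot sample in an otherwise flat region of a two-level volume:
        # vertices on the plateau get the geometric (triangle) normal fallback
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        mesh = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=False)
        assert np.abs(np.linalg.norm(mesh.normals, axis=1) - 1).max() < 1e-9

    def test_linear_ramp_gradient_as_printed(self):
        zs, ys, xs = np.mgrid[0:6, 0:6, 0:6].astype(float)
        vol = sr.Volume(xs, (1, 1, 1))
        g = sr.vertex_gradient(vol, (3, 2, 2))
        # central difference without the conventional 1/2: (i+1)-(i-1) = 2
        assert np.allclose(g, (2.0, 0.0, 0.0))

    def test_sphere_gradients_near_radial(self, sphere_spec):
        vol = sr.generate_field(sphere_spec)
        bright = bright_field(vol)
        mesh = sr.extract_isosurface(bright, 0.0)
        c = np.asarray(sphere_spec.shape_params["center"])
        radial = mesh.vertices - c
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.einsum("ij,ij->i", mesh.normals, radial)
        angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert angles.max() < 2.0


class TestExtraction:
    def test_all_below_yields_empty_mesh(self):
        mesh = sr.extract_isosurface(sr.Volume(np.zeros((4, 4, 4)), (1, 1, 1)), 5.0)
        assert mesh.n_triangles == 0 and mesh.n_vertices == 0

    def test_single_hot_sample_yields_octahedron(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        mesh = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=False)
        assert mesh.n_vertices == 6 and mesh.n_triangles == 8
        report = sr.watertight_check(mesh)
        assert report.is_closed
        assert sr.euler_characteristic(mesh) == 2

    def test_sphere_volume_within_two_percent(self, sphere_spec):
        mesh = sr.extract_isosurface(bright_field(sr.generate_field(sphere_spec)), 0.0)
        vol = sr.enclosed_volume(mesh)
        assert abs(vol - 4188.79) / 4188.79 < 0.02

    @pytest.mark.parametrize("phantom,expected_euler", [("sphere", 2), ("torus", 0), ("tube", 2)])
    def test_phantom_topology(self, phantom, expected_euler, request):
        spec = request.getfixturevalue(f"{phantom}_spec")
        mesh = sr.extract_isosurface(bright_field(sr.generate_field(spec)), 0.0)
        assert sr.watertight_check(mesh).is_closed
        assert sr.euler_characteristic(mesh) == expected_euler

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(size=(7, 7, 7))
        m1 = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.4, pad=False)
        m2 = sr.extract_isosurface(sr.Volume(-data, (1, 1, 1)), -0.4, pad=False)
        v1 = {tuple(np.round(v, 9)) for v in m1.vertices}
        v2 = {tuple(np.round(v, 9)) for v in m2.vertices}
        assert v1 == v2
        # orientation is opposite: signed volumes negate
        def signed(m):
            v, t = m.vertices, m.triangles
            return np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum()
        assert signed(m1) == pytest.approx(-signed(m2), rel=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(size=(6, 6, 6))
        a = sr.extract_isosurface(sr.Volume(data, (1, 1, 1), origin=(0, 0, 0)), 0.5, pad=False)
        b = sr.extract_isosurface(
            sr.Volume(data, (1, 1, 1), origin=(2.5, -1.0, 7.0)), 0.5, pad=False
        )
        assert np.array_equal(a.triangles, b.triangles)
        assert np.allclose(b.vertices - a.vertices, [2.5, -1.0, 7.0])

    def test_convergence_on_sphere(self):
        errors = []
        for h in (2.0, 1.0, 0.5):
            n = int(round(28 / h)) + 3
            c = ((n - 1) * h / 2 + 0.3, (n - 1) * h / 2 - 0.2, (n - 1) * h / 2 + 0.1)
            spec = sr.PhantomSpec("sphere", {"radius": 10.0, "center": c}, (n, n, n), (h, h, h))
            mesh = sr.extract_isosurface(bright_field(sr.generate_field(spec)), 0.0)
            errors.append(abs(sr.enclosed_volume(mesh) - 4188.79) / 4188.79)
        assert errors[0] > errors[1] > errors[2]

    def test_boundary_autopad_closes_clipped_surface(self):
        data = np.full((5, 5, 5), 1.0)  # everything above isovalue
        clipped = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=False)
        assert clipped.n_triangles == 0
        padded = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=True)
        assert sr.watertight_check(padded).is_closed
        assert sr.euler_characteristic(padded) == 2


class TestOracleEquivalence:
    """Per-cube intersected-edge sets match an independent isosurfacer."""

    @staticmethod
    def edge_keys(verts, flip_zyx):
        keys = set()
        for p in verts:
            q = p[::-1] if flip_zyx else p
            frac = q - np.floor(q)
            axes = [i for i in range(3) if 1e-9 < frac[i] < 1 - 1e-9]
            assert len(axes) == 1
            keys.add((axes[0], int(q[0] // 1), int(q[1] // 1), int(q[2] // 1)))
        return keys

    def test_edge_sets_match_reference(self):
        marching_cubes = pytest.importorskip("skimage.measure").marching_cubes
        rng = np.random.default_rng(42)
        for _ in range(25):
            data = np.zeros((8, 8, 8))
            data[1:-1, 1:-1, 1:-1] = rng.uniform(size=(6, 6, 6))
            mine = sr.extract_isosurface(sr.Volume(data, (1, 1, 1)), 0.5, pad=False)
            ref_verts, _, _, _ = marching_cubes(data, 0.5, method="lorensen")
            assert self.edge_keys(mine.vertices, False) == self.edge_keys(ref_verts, True)
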