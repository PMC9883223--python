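import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terracemark import marching
from terracemark.marching import (
    CORNER_OFFSETS,
    EDGE_CORNERS,
    EDGE_MIDPOINTS,
    CellConfiguration,
    TriangleMesh,
    count_cube_equivalence_classes,
    extract_isosurface,
    load_mesh,
    marching_cubes_table,
    marching_squares_table,
    save_mesh,
    smooth_preserving_plateaus,
)


class TestSquareTable:
    def test_sixteen_entries(self):
        assert len(marching_squares_table()) == 16

    def test_homogeneous_configurations_are_empty(self):
        table = marching_squares_table()
        assert table[0] == frozenset() and table[15] == frozenset()

    def test_single_corner_yields_one_clipping_segment(self):
        table = marching_squares_table()
        (seg,) = table[1]  # corner (0,0) inside
        assert set(seg) == {(0.5, 0.0), (0.0, 0.5)}

    def test_complementary_configurations_identical(self):
        table = marching_squares_table()
        for idx in range(16):
            assert table[idx] == table[15 - idx]

    def test_saddles_resolved_by_separating_main_diagonal(self):
        table = marching_squares_table()
        expected = frozenset({tuple(sorted([(0.5, 0.0), (0.0, 0.5)])),
                              tuple(sorted([(1.0, 0.5), (0.5, 1.0)]))})
        assert table[0b1001] == expected  # corners (0,0) and (1,1) inside
        assert table[0b0110] == expected

    def test_segment_endpoints_are_edge_midpoints(self):
        mids = {(0.5, 0.0), (0.0, 0.5), (1.0, 0.5), (0.5, 1.0)}
        for segs in marching_squares_table().values():
            for seg in segs:
                assert set(seg) <= mids


class TestCubeTable:
    def test_256_entries_homogeneous_empty(self):
        table = marching_cubes_table()
        assert len(table) == 256
        assert table[0] == () and table[255] == ()

    def test_single_corner_clipped_by_one_triangle(self):
        (tri,) = marching_cubes_table()[1]
        # vertices are the midpoints of corner 0's three edges
        mids = {tuple(EDGE_MIDPOINTS[e]) for e in tri}
        assert mids == {(0.5, 0.0, 0.0), (0.0, 0.5, 0.0), (0.0, 0.0, 0.5)}

    def test_every_nonhomogeneous_entry_has_one_to_five_triangles(self):
        table = marching_cubes_table()
        counts = [len(table[i]) for i in range(1, 255)]
        assert min(counts) >= 1 and max(counts) <= 5

    def test_triangle_vertices_lie_on_cut_edges(self):
        table = marching_cubes_table()
        for idx, tris in table.items():
            inside = {c for c in range(8) if idx >> c & 1}
            cut = {e for e, (a, b) in enumerate(EDGE_CORNERS)
                   if (a in inside) != (b in inside)}
            used = {e for tri in tris for e in tri}
            assert used == cut, f"config {idx}"

    def test_orientation_on_planar_representative_configs(self):
        """Triangles face from tissue toward air on every planar pattern:
        the 8 single-corner clips, their complements, and the 6 half-space
        splits (one full voxel layer inside)."""
        table = marching_cubes_table()
        for corner in range(8):
            for idx in (1 << corner, 255 - (1 << corner)):
                for tri in table[idx]:
                    pts = EDGE_MIDPOINTS[list(tri)]
                    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
                    away = pts.mean(axis=0) - CORNER_OFFSETS[corner]
                    sign = 1 if idx == 1 << corner else -1
                    assert sign * np.dot(normal, away) > 0, f"config {idx}"
        # half-space splits: e.g. bottom layer (z=0) inside -> normals +z
        layers = {0b00001111: (0, 0, 1), 0b11110000: (0, 0, -1),
                  0b00110011: (0, 1, 0), 0b11001100: (0, -1, 0),
                  0b01010101: (1, 0, 0), 0b10101010: (-1, 0, 0)}
        for idx, expected in layers.items():
            for tri in table[idx]:
                pts = EDGE_MIDPOINTS[list(tri)]
                normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
                assert np.dot(normal, expected) > 0, f"config {idx:08b}"

    def test_polygon_orientation_separates_inside_from_outside(self):
        """Each contour polygon's Newell normal points away from the inside
        corners it bounds, for all 254 mixed configurations."""
        from terracemark.marching import _cell_polygons, _newell_normal, _orient_and_fan

        for idx in range(1, 255):
            inside = frozenset(c for c in range(8) if idx >> c & 1)
            for cycle in _cell_polygons(inside):
                tris = _orient_and_fan(cycle, inside)
                # reconstruct the oriented cycle from the fan
                ordered = [tris[0][0]] + [t[1] for t in tris] + [tris[-1][2]]
                normal = _newell_normal(EDGE_MIDPOINTS[ordered])
                ins = [a if a in inside else b
                       for a, b in (EDGE_CORNERS[e] for e in cycle)]
                ins_mean = CORNER_OFFSETS[ins].mean(axis=0)
                centroid = EDGE_MIDPOINTS[ordered].mean(axis=0)
                assert np.dot(normal, ins_mean - centroid) < 0, f"config {idx}"


class TestEquivalenceClasses:
    def test_fifteen_unique_patterns_under_rotation_and_complement(self):
        assert count_cube_equivalence_classes("rotation+complement") == 15

    def test_twenty_three_under_rotation_alone(self):
        assert count_cube_equivalence_classes("rotation") == 23

    def test_burnside_cross_check(self):
        """Orbit counts recomputed independently from cycle structures."""
        perms = marching._rotation_corner_permutations()
        assert len(perms) == 24

        def cycles(perm):
            seen, out = set(), []
            for s in range(8):
                if s in seen:
                    continue
                n, c = s, 0
                while n not in seen:
                    seen.add(n)
                    n, c = perm[n], c + 1
                out.append(c)
            return out

        rot_sum = sum(2 ** len(cycles(p)) for p in perms)
        assert rot_sum // 24 == 23
        # rotation*complement elements fix a coloring iff all cycles are even
        comp_sum = sum(np.prod([2 if c % 2 == 0 else 0 for c in cycles(p)])
                       for p in perms)
        assert (rot_sum + comp_sum) // 48 == 15

    def test_homogeneous_configs_merge_only_under_complement(self):
        perms = marching._rotation_corner_permutations()
        orbit0 = {marching._apply_corner_perm(0, p) for p in perms}
        orbit255 = {marching._apply_corner_perm(255, p) for p in perms}
        assert orbit0 == {0} and orbit255 == {255}  # two classes under rotation
        assert 255 - 0 == 255  # complement maps one onto the other: one class

    def test_cell_configuration_index_encoding(self):
        cfg = CellConfiguration(3, (True,) + (False,) * 6 + (True,))
        assert cfg.index == 1 + 128
        with pytest.raises(ValueError):
            CellConfiguration(2, (True,) * 8)


class TestExtraction:
    def test_single_interior_voxel_is_an_octahedron(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = extract_isosurface(mask)
        assert mesh.n_vertices == 6
        assert len(mesh.faces) == 8
        assert len(mesh.edges()) == 12
        assert mesh.euler_characteristic() == 2
        assert mesh.is_watertight()
        assert not mesh.open_boundary
        # outward normals point away from the voxel center
        outward = np.einsum("ij,ij->i", mesh.vertex_normals, mesh.vertices - 2.0)
        assert (outward > 0).all()

    def test_ball_watertight_euler_two(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2

    def test_vertex_set_matches_skimage(self, ball_mask):
        from skimage import measure

        mesh = extract_isosurface(ball_mask)
        sk_verts, _, _, _ = measure.marching_cubes(ball_mask.astype(float), level=0.5)
        ours = set(map(tuple, np.round(mesh.vertices, 6)))
        theirs = set(map(tuple, np.round(sk_verts, 6)))
        assert ours == theirs

    def test_all_vertices_on_edge_midpoints(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        doubled = 2.0 * mesh.vertices
        assert np.allclose(doubled, np.round(doubled))
        # exactly one half-integer coordinate per vertex
        assert (np.sum(mesh.vertices % 1 == 0.5, axis=1) == 1).all()

    def test_complement_same_vertices_flipped_normals(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        comp = extract_isosurface(~ball_mask)
        key = lambda m: np.lexsort(m.vertices.T[::-1])
        vi, ci = key(mesh), key(comp)
        assert np.array_equal(mesh.vertices[vi], comp.vertices[ci])
        # normals reverse; where ambiguous faces are re-triangulated the
        # area weights shift, so assert opposition, not exact negation
        dots = np.einsum("ij,ij->i", mesh.vertex_normals[vi], comp.vertex_normals[ci])
        assert (dots < 0).all()
        assert comp.open_boundary  # complement foreground touches the grid

    def test_complement_normals_exactly_flipped_on_single_voxel(self):
        """Around one voxel every polygon is a single triangle, so the
        complement's octahedron negates the normals exactly."""
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = extract_isosurface(mask)
        comp = extract_isosurface(~mask)
        key = lambda m: np.lexsort(m.vertices.T[::-1])
        vi, ci = key(mesh), key(comp)
        assert np.array_equal(mesh.vertices[vi], comp.vertices[ci])
        assert np.allclose(mesh.vertex_normals[vi], -comp.vertex_normals[ci],
                           atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_translation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        blob = np.zeros((14, 14, 14), bool)
        blob[4:9, 4:9, 4:9] = rng.random((5, 5, 5)) < 0.6
        blob[6, 6, 6] = True
        mesh = extract_isosurface(blob)
        shifted = extract_isosurface(np.roll(blob, (2, 1, 3), axis=(0, 1, 2)))
        key = lambda v: sorted(map(tuple, np.round(v, 6)))
        assert key(shifted.vertices) == key(mesh.vertices + (2, 1, 3))

    def test_watertight_on_random_interior_blobs(self):
        rng = np.random.default_rng(99)
        from scipy import ndimage

        for _ in range(5):
            blob = np.zeros((16, 16, 16), bool)
            blob[5:11, 5:11, 5:11] = rng.random((6, 6, 6)) < 0.5
            blob[8, 8, 8] = True
            labels, _ = ndimage.label(blob, np.ones((3, 3, 3)))
            blob = labels == labels[8, 8, 8]  # keep one 26-connected component
            mesh = extract_isosurface(blob)
            assert mesh.is_watertight()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_isosurface(np.zeros((4, 4, 4), bool))

    def test_plateau_is_planar_with_vertical_normals(self, step_pyramid_mask):
        mesh = extract_isosurface(step_pyramid_mask)
        # top plateau: vertical cut edges above the top tier (z = 8.5)
        top = mesh.vertices[:, 2] == mesh.vertices[:, 2].max()
        assert top.sum() >= 25
        normals = mesh.vertex_normals[top]
        # interior plateau vertices point exactly +z; rim vertices tilt
        interior = top & (np.abs(mesh.vertices[:, 0] - 20) < 4) \
            & (np.abs(mesh.vertices[:, 1] - 20) < 4)
        assert np.allclose(mesh.vertex_normals[interior], (0, 0, 1))
        assert (normals[:, 2] > 0).all()


class TestSmoothing:
    def test_zero_iterations_is_identity(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        out = smooth_preserving_plateaus(mesh, 0)
        assert out is mesh

    def test_positions_never_change(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        out = smooth_preserving_plateaus(mesh, 5)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.allclose(np.linalg.norm(out.vertex_normals, axis=1), 1.0, atol=1e-9)

    def test_plateau_interior_is_fixed_point(self, step_pyramid_mask):
        mesh = extract_isosurface(step_pyramid_mask)
        out = smooth_preserving_plateaus(mesh, 3)
        interior = (mesh.vertices[:, 2] == mesh.vertices[:, 2].max()) \
            & (np.abs(mesh.vertices[:, 0] - 20) < 4) \
            & (np.abs(mesh.vertices[:, 1] - 20) < 4)
        assert np.allclose(out.vertex_normals[interior],
                           mesh.vertex_normals[interior], atol=1e-12)

    def test_staircase_noise_on_wall_converges_to_wall_normal(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((40, 40, 12), bool)
        mask[2:38, 2:38, 2:6] = True  # flat wall facing +z
        # sprinkle single-voxel staircase noise on the wall
        for _ in range(25):
            i, j = rng.integers(5, 35, size=2)
            mask[i, j, 6] = True
        mesh = extract_isosurface(mask)
        smoothed = smooth_preserving_plateaus(mesh, 4)
        wall = (mesh.vertices[:, 2] == 5.5) \
            & (mesh.vertices[:, 0] > 4) & (mesh.vertices[:, 0] < 36) \
            & (mesh.vertices[:, 1] > 4) & (mesh.vertices[:, 1] < 36)
        cos_angle = smoothed.vertex_normals[wall] @ np.array([0.0, 0.0, 1.0])
        assert (cos_angle >= np.cos(np.deg2rad(10))).all()

    def test_negative_iterations_rejected(self, ball_mask):
        with pytest.raises(ValueError):
            smooth_preserving_plateaus(extract_isosurface(ball_mask), -1)


class TestMeshIO:
    @pytest.mark.parametrize("suffix", [".ply", ".obj"])
    def test_round_trip(self, tmp_path, ball_mask, suffix):
        mesh = extract_isosurface(ball_mask)
        path = tmp_path / f"mesh{suffix}"
        save_mesh(mesh, path, ascii=True)
        back = load_mesh(path)
        assert back.n_vertices == mesh.n_vertices
        assert len(back.faces) == len(mesh.faces)
        key = lambda v: sorted(map(tuple, np.round(v, 4)))
        assert key(back.vertices) == key(mesh.vertices)

    def test_mesh_invariants(self, ball_mask):
        mesh = extract_isosurface(ball_mask)
        assert mesh.faces.min() >= 0 and mesh.faces.max() < mesh.n_vertices
        assert (np.sort(mesh.faces, axis=1)[:, :-1]
                != np.sort(mesh.faces, axis=1)[:, 1:]).all()  # distinct indices
        assert np.allclose(np.linalg.norm(mesh.vertex_normals, axis=1), 1, atol=1e-6)
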