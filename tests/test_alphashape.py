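"""Alpha-shape construction: circumradii, filtering, surfaces, volumes."""

import numpy as np
import pytest

import solidnma as s
from solidnma.errors import (
    BracketingError,
    DegenerateGeometryError,
    EmptyShapeError,
)

RIGHT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])

from hypothesis import given, settings
from hypothesis import strategies as st

coord = st.floats(-50, 50, allow_nan=False, width=32)
tet_strategy = st.lists(
    st.tuples(coord, coord, coord), min_size=4, max_size=4
).map(np.array)


@settings(max_examples=60, derandomize=True)
@given(tet_strategy, st.tuples(coord, coord, coord))
def test_circumradius_properties(tet, shift):
    """R bounds and rigid invariance for any non-degenerate tetrahedron."""
    vol = s.alphashape.tet_volumes(tet, np.array([[0, 1, 2, 3]]))[0]
    if vol < 1e-3:
        return  # degenerate inputs are covered by the error-path test
    r = s.circumradius(*tet)
    from scipy.spatial.distance import pdist

    # circumsphere contains all vertices: R ≥ half the longest edge
    assert r >= pdist(tet).max() / 2 - 1e-9
    assert s.circumradius(*(tet + np.asarray(shift))) == pytest.approx(
        r, rel=1e-6, abs=1e-9
    )


class TestCircumradius:
    def test_unit_right_corner_tet(self):
        assert s.circumradius(*RIGHT_TET) == pytest.approx(np.sqrt(3) / 2)

    def test_regular_tet_closed_form(self):
        # edge a=2: R = a·√(3/8)
        a = 2.0
        tet = a * np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
             [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]
        )
        assert s.circumradius(*tet) == pytest.approx(a * np.sqrt(3.0 / 8.0))

    def test_random_tets_match_equidistance_solve(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            if s.alphashape.tet_volumes(pts, np.array([[0, 1, 2, 3]]))[0] < 1e-6:
                continue
            r = s.circumradius(*pts)
            # oracle: least-squares solve of the 4-point equidistance system
            # |c - p_i|² equal for all i  ⇔  2(p_i - p_0)·c = |p_i|² - |p_0|²
            a = 2 * (pts[1:] - pts[0])
            b = (pts[1:] ** 2).sum(axis=1) - (pts[0] ** 2).sum()
            c, *_ = np.linalg.lstsq(a, b, rcond=None)
            radii = np.linalg.norm(pts - c, axis=1)
            assert np.allclose(radii, radii[0])
            assert r == pytest.approx(radii[0], rel=1e-9)

    def test_coplanar_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            s.circumradius(*flat)


class TestBuildAlphaShape:
    def test_lattice_full_retention(self, lattice3):
        mesh = s.build_alpha_shape(lattice3, 10.0)
        assert mesh.volume == pytest.approx(8.0)
        assert np.all(mesh.radii <= 10.0)
        assert len(mesh.used_nodes) == 27

    def test_alpha_infinity_equals_delaunay_hull(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(60, 3))
        mesh = s.build_alpha_shape(pts, np.inf)
        from scipy.spatial import ConvexHull

        assert mesh.volume == pytest.approx(ConvexHull(pts).volume, rel=1e-6)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, size=(80, 3))
        tet_sets, vols = [], []
        for alpha in (2.0, 3.0, 5.0, np.inf):
            m = s.build_alpha_shape(pts, alpha)
            tet_sets.append({tuple(sorted(t)) for t in m.tets.tolist()})
            vols.append(m.volume)
        for small, big in zip(tet_sets, tet_sets[1:]):
            assert small <= big
        assert vols == sorted(vols)

    def test_gap_separates_components(self):
        a = s.make_lattice(3).coords
        b = a + [20.0, 0, 0]
        mesh = s.build_alpha_shape(np.vstack([a, b]), 2.0)
        comps = s.connected_components(mesh)
        assert len(comps) == 2
        # no bridging tet: any tet spanning the 20 Å gap would need a
        # circumsphere at least half the gap in radius
        assert sorted(len(c.used_nodes) for c in comps) == [27, 27]
        assert sum(len(c.used_nodes) for c in comps) == len(mesh.used_nodes)

    def test_too_small_alpha_raises(self, lattice3):
        with pytest.raises(EmptyShapeError):
            s.build_alpha_shape(lattice3, 0.1)

    def test_coplanar_cloud_raises(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(30, 2)),
                               np.zeros(30)])
        with pytest.raises(DegenerateGeometryError):
            s.build_alpha_shape(pts, 1.0)


class TestCriticalAlpha:
    def test_single_tet(self):
        assert s.critical_alpha(RIGHT_TET) == pytest.approx(np.sqrt(3) / 2)

    def test_brute_force_over_radius_candidates(self, lattice3):
        # oracle: smallest candidate alpha (sorted unique circumradii) whose
        # filtered shape touches every point
        from scipy.spatial import Delaunay

        coords = lattice3.coords
        tri = Delaunay(coords)
        vols = s.alphashape.tet_volumes(coords, tri.simplices)
        tets = tri.simplices[vols >= 1e-9]
        radii = s.alphashape.circumradii(coords, tets)
        best = None
        for cand in np.sort(np.unique(radii)):
            used = np.unique(tets[radii <= cand])
            if len(used) == len(coords):
                best = cand
                break
        assert s.critical_alpha(coords) == pytest.approx(best)
        mesh = s.build_alpha_shape(coords, None)
        assert len(mesh.used_nodes) == len(coords)

    def test_outlier_increases_value(self, lattice3):
        base = s.critical_alpha(lattice3.coords)
        with_outlier = np.vstack([lattice3.coords, [[15.0, 15.0, 15.0]]])
        assert s.critical_alpha(with_outlier) > base


class TestSurfaceAndVolume:
    def test_single_tet_four_boundary_triangles(self):
        mesh = s.TetMesh(RIGHT_TET, np.array([[0, 1, 2, 3]]))
        assert len(s.boundary_surface(mesh).triangles) == 4
        assert s.shape_volume(mesh) == pytest.approx(1 / 6)

    def test_two_tets_sharing_face(self):
        nodes = np.vstack([RIGHT_TET, [[1, 1, 1.0]]])
        mesh = s.TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        assert len(s.boundary_surface(mesh).triangles) == 6

    def test_lattice_cube_area_and_volume(self):
        lat = s.make_lattice(4, spacing=2.0)
        mesh = s.build_alpha_shape(lat, 20.0)
        L = 3 * 2.0
        assert mesh.volume == pytest.approx(L**3, rel=1e-9)
        surf = s.boundary_surface(mesh)
        assert surf.area == pytest.approx(6 * L**2, rel=0.01)

    def test_watertight_boundary(self, lattice3):
        surf = s.boundary_surface(s.build_alpha_shape(lattice3, 10.0))
        edges = np.sort(
            surf.triangles[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert set(counts.tolist()) == {2}

    def test_outward_orientation_encloses_volume(self, lattice3):
        mesh = s.build_alpha_shape(lattice3, 10.0)
        surf = s.boundary_surface(mesh)
        p = surf.nodes[surf.triangles]
        signed = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6
        assert signed == pytest.approx(mesh.volume, rel=1e-9)


class TestAlphaForVolume:
    def test_fixed_point(self, lattice3):
        v = s.build_alpha_shape(lattice3, 0.9).volume
        a = s.alpha_for_volume(lattice3, v)
        assert s.build_alpha_shape(lattice3, a).volume == pytest.approx(v)

    def test_full_volume_saturates(self, lattice3):
        a = s.alpha_for_volume(lattice3, 8.0)
        mesh = s.build_alpha_shape(lattice3, a)
        assert mesh.volume == pytest.approx(8.0)

    def test_unattainable_target_raises(self, lattice3):
        with pytest.raises(BracketingError):
            s.alpha_for_volume(lattice3, 100.0)

    def test_cross_resolution_volume_matching(self):
        # matching a finer model's volume with a coarser model's alpha, the
        # workflow used to keep solids consistent across coarse-graining
        fine = s.make_lattice(7)
        coarse = fine.take(np.arange(0, len(fine), 3))
        target = s.build_alpha_shape(fine, 2.0).volume
        a = s.alpha_for_volume(coarse, target, rtol=0.1)
        got = s.build_alpha_shape(coarse, a).volume
        assert got == pytest.approx(target, rel=0.1)


class TestExportImport:
    @pytest.mark.parametrize("fmt", ["vtk", "inp", "msh"])
    def test_round_trip(self, tmp_path, lattice3, fmt):
        mesh = s.build_alpha_shape(lattice3, 10.0)
        path = tmp_path / f"mesh.{fmt}"
        s.export_mesh(mesh, path, fmt)
        back = s.import_mesh(path, fmt)
        assert np.allclose(back.nodes, mesh.nodes, atol=1e-5)
        assert np.array_equal(back.tets, mesh.tets)
        assert back.volume == pytest.approx(mesh.volume, rel=1e-6)

    def test_inp_counts_and_one_based_indices(self, tmp_path, lattice3):
        mesh = s.build_alpha_shape(lattice3, 10.0)
        path = tmp_path / "mesh.inp"
        s.export_mesh(mesh, path, "inp")
        text = path.read_text()
        node_lines = text.split("*NODE\n")[1].split("*ELEMENT")[0].strip().splitlines()
        elem_lines = text.split("TYPE=C3D4\n")[1].strip().splitlines()
        assert len(node_lines) == mesh.n_nodes
        assert len(elem_lines) == mesh.n_tets
        first_elem = [int(v) for v in elem_lines[0].split(",")]
        assert min(first_elem[1:]) >= 1

    def test_unknown_format(self, lattice3):
        mesh = s.build_alpha_shape(lattice3, 10.0)
        with pytest.raises(ValueError):
            s.export_mesh(mesh, "/tmp/x.bad", "stl")
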