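"""Static response, extents, indentation surrogate, AFM calibration."""

import numpy as np
import pytest

import solidnma as s
from solidnma.errors import UnderConstrainedError


@pytest.fixture(scope="module")
def bar_system():
    bar = s.make_bar(20, 3, 3, spacing=1.5)
    mesh = s.build_alpha_shape(bar, 3.0)
    params = s.ElasticParams.for_mesh(mesh, bar.total_mass, E=1.0, nu=0.0)
    return bar, mesh, s.assemble(mesh, params)


def clamp_end(bar):
    return np.nonzero(bar.coords[:, 0] < 0.1)[0]


class TestStaticSolve:
    def test_zero_force_zero_displacement(self, bar_system):
        bar, _, system = bar_system
        bc = s.BoundaryCondition(fixed_nodes=clamp_end(bar))
        res = s.static_solve(system, bc)
        assert np.abs(res.displacements).max() == 0.0

    def test_linearity(self, bar_system):
        bar, _, system = bar_system
        tip = int(np.argmax(bar.coords[:, 0]))
        bc1 = s.BoundaryCondition(
            fixed_nodes=clamp_end(bar), forces={tip: np.array([0, 0, 0.01])}
        )
        bc2 = s.BoundaryCondition(
            fixed_nodes=clamp_end(bar), forces={tip: np.array([0, 0, 0.02])}
        )
        u1 = s.static_solve(system, bc1).displacements
        u2 = s.static_solve(system, bc2).displacements
        assert np.allclose(u2, 2 * u1, atol=1e-12)

    def test_axial_tip_displacement_closed_form(self):
        # clamped bar, axial end load: u = FL/(EA) within 5%
        bar = s.make_bar(41, 3, 3, spacing=1.0)
        mesh = s.build_alpha_shape(bar, 2.0)
        params = s.ElasticParams.for_mesh(mesh, bar.total_mass, E=2.0, nu=0.0)
        system = s.assemble(mesh, params)
        L, A = 40.0, 4.0  # cross-section (3−1)² spacing²
        tips = np.nonzero(bar.coords[:, 0] > L - 0.1)[0]
        F = 0.05
        bc = s.BoundaryCondition(
            fixed_nodes=clamp_end(bar),
            forces={int(n): np.array([F / len(tips), 0, 0]) for n in tips},
        )
        res = s.static_solve(system, bc)
        u_tip = res.displacements[tips, 0].mean()
        assert u_tip == pytest.approx(F * L / (params.E * A), rel=0.05)

    def test_equilibrium_and_energy(self, bar_system):
        bar, _, system = bar_system
        rng = np.random.default_rng(4)
        loaded = rng.choice(
            np.nonzero(bar.coords[:, 0] > 5)[0], size=6, replace=False
        )
        bc = s.BoundaryCondition(
            fixed_nodes=clamp_end(bar),
            forces={int(n): rng.normal(size=3) * 0.01 for n in loaded},
        )
        res = s.static_solve(system, bc)
        total_applied = np.linalg.norm(res.applied.reshape(-1, 3).sum(axis=0))
        assert np.linalg.norm(res.force_balance()) < 1e-6 * total_applied
        u = res.u_flat
        strain = 0.5 * u @ (system.K @ u)
        work = 0.5 * res.applied @ u
        assert strain == pytest.approx(work, rel=1e-8)

    def test_superposition(self, bar_system):
        bar, _, system = bar_system
        tip = int(np.argmax(bar.coords[:, 0]))
        mid = int(np.argmin(np.abs(bar.coords[:, 0] - 15)))
        fixed = clamp_end(bar)
        f1 = {tip: np.array([0, 0.01, 0.0])}
        f2 = {mid: np.array([0.02, 0, 0.01])}
        u1 = s.static_solve(system, s.BoundaryCondition(fixed, f1)).displacements
        u2 = s.static_solve(system, s.BoundaryCondition(fixed, f2)).displacements
        u12 = s.static_solve(
            system, s.BoundaryCondition(fixed, {**f1, **f2})
        ).displacements
        assert np.allclose(u12, u1 + u2, atol=1e-10)

    def test_unconstrained_raises(self, bar_system):
        bar, _, system = bar_system
        tip = int(np.argmax(bar.coords[:, 0]))
        bc = s.BoundaryCondition(forces={tip: np.array([0, 0, 0.01])})
        with pytest.raises(UnderConstrainedError):
            s.static_solve(system, bc)


class TestExtents:
    def test_pure_translation_field(self):
        res = s.DeformationResult(
            displacements=np.tile([0.0, 0.0, 0.7], (10, 1)),
            reactions=np.zeros(0),
            constrained_dofs=np.zeros(0, dtype=int),
            applied=np.zeros(30),
        )
        ext = s.deformation_extents(res, axis=2)
        assert np.allclose(ext["extent_axis"], 0.7)
        assert np.allclose(ext["extent_plane"], 0.0)

    def test_frame_change_consistency(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(15, 3))
        res = lambda d: s.DeformationResult(d, np.zeros(0), np.zeros(0, int),
                                            np.zeros(45))
        ext_z = s.deformation_extents(res(u), axis=2)
        swapped = u[:, [2, 1, 0]]
        ext_x = s.deformation_extents(res(swapped), axis=0)
        assert np.allclose(ext_z["extent_axis"], ext_x["extent_axis"])
        assert np.allclose(ext_z["extent_plane"], ext_x["extent_plane"])

    def test_solid_deforms_axially_under_axial_load(self):
        # pressing down on the top of a solid slab moves it mostly along
        # the push axis (the contrast highlighted against spring networks)
        slab = s.make_bar(7, 7, 4, spacing=1.5)
        mesh = s.build_alpha_shape(slab, 3.0)
        system = s.assemble(
            mesh, s.ElasticParams.for_mesh(mesh, slab.total_mass, nu=0.3)
        )
        base = np.nonzero(slab.coords[:, 2] < 0.1)[0]
        top = np.nonzero(slab.coords[:, 2] > 4.4)[0]
        bc = s.BoundaryCondition(
            fixed_nodes=base,
            forces={int(n): np.array([0, 0, -0.01]) for n in top},
        )
        ext = s.deformation_extents(s.static_solve(system, bc), axis=2)
        assert ext["max_axis"] > 2 * ext["max_plane"]


class TestIndentation:
    @pytest.fixture(scope="class")
    def shells(self):
        out = {}
        for th in (3.0, 5.0):
            pts = s.make_shell(12.0, th, spacing=1.5, hemisphere=True)
            out[th] = (pts, s.build_alpha_shape(pts, 2.5))
        return out

    def test_slope_invariant_in_E(self, shells):
        pts, mesh = shells[3.0]
        kappas = []
        for E in (1.0, 7.0):
            params = s.ElasticParams.for_mesh(mesh, pts.total_mass, E=E)
            kappas.append(
                s.indentation_stiffness(mesh, params, tip_radius=8.0,
                                        contact_depth_step=0.5)
            )
        assert kappas[0] == pytest.approx(kappas[1], rel=1e-9)

    def test_thicker_shell_is_stiffer(self, shells):
        slopes = {}
        for th, (pts, mesh) in shells.items():
            params = s.ElasticParams.for_mesh(mesh, pts.total_mass)
            slopes[th] = s.indentation_stiffness(
                mesh, params, tip_radius=8.0, contact_depth_step=0.5
            )
        assert slopes[5.0] > slopes[3.0] > 0

    def test_matches_direct_prescribed_displacement_solve(self):
        # flat slab: small-depth reaction must equal a static_solve with the
        # equivalent prescribed displacements
        slab = s.make_bar(9, 9, 3, spacing=1.5)
        mesh = s.build_alpha_shape(slab, 3.0)
        params = s.ElasticParams.for_mesh(mesh, slab.total_mass)
        system = s.assemble(mesh, params, warn_disconnected=False)
        depth, tip_r = 0.4, 5.0
        kappa = s.indentation_stiffness(
            mesh, params, tip_radius=tip_r, contact_depth_step=depth,
            base_fraction=0.2, system=system,
        )
        z = slab.coords[:, 2]
        zmax, zmin = z.max(), z.min()
        centroid = slab.coords.mean(axis=0)
        rho = np.linalg.norm(slab.coords[:, :2] - centroid[:2], axis=1)
        z_c = zmax + tip_r - depth
        surf = z_c - np.sqrt(np.clip(tip_r**2 - rho**2, 0, None))
        pen = z - surf
        base = np.nonzero(z <= zmin + 0.2 * (zmax - zmin))[0]
        pres = {
            3 * int(n) + 2: -float(pen[n])
            for n in np.nonzero((rho < tip_r) & (pen > 0))[0]
            if n not in set(base.tolist())
        }
        res = s.static_solve(
            system, s.BoundaryCondition(fixed_nodes=base, prescribed=pres)
        )
        sel = np.isin(res.constrained_dofs, np.array(sorted(pres)))
        force = abs(res.reactions[sel].sum())
        assert kappa == pytest.approx(force / depth / params.E / 10.0, rel=1e-9)


class TestAfmCalibration:
    def test_reference_arithmetic(self):
        assert s.young_from_afm(0.65, 0.15) == pytest.approx(0.23, abs=0.005)

    def test_unit_ratio(self):
        assert s.young_from_afm(0.4, 0.4) == 1.0

    def test_linearity(self):
        assert s.young_from_afm(0.5, 0.3) == pytest.approx(
            2 * s.young_from_afm(0.5, 0.15)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            s.young_from_afm(0.0, 0.1)
        with pytest.raises(ValueError):
            s.young_from_afm(0.5, -1.0)
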