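import numpy as np
import pytest
from scipy.special import eval_legendre, spherical_in

from fdot.da import (DASolver, assemble_measurement_vector_da, tag_patches,
                     voxel_to_mesh)
from fdot.geometry import OptodeLayout, VoxelHeadModel
from fdot.mesh import ball_mesh
from fdot.optical import (OpticalTable, Tissue, TissueOpticalProperties,
                          effective_reflection)

from conftest import homogeneous_table


def ball_series_solution(points, R, mu_a, mu_sp, rho, patch_radius=1.5,
                         n_terms=120):
    """Exact Legendre-Bessel series for the CW diffusion problem on a
    homogeneous ball with a polar-cap diffuse source of unit strength."""
    kappa = 1.0 / (3.0 * (mu_a + mu_sp))
    k = np.sqrt(mu_a / kappa)
    th0 = patch_radius / R
    c0 = np.cos(th0)
    area = 2 * np.pi * R ** 2 * (1 - c0)
    ls = np.arange(n_terms + 1)
    intP = np.empty(n_terms + 1)
    intP[0] = 1 - c0
    for l in range(1, n_terms + 1):
        intP[l] = (eval_legendre(l - 1, c0) - eval_legendre(l + 1, c0)) / (2 * l + 1)
    q_l = (2 * ls + 1) / 2 * intP / area
    il = spherical_in(ls, k * R)
    dil = spherical_in(ls, k * R, derivative=True) * k
    c_l = 4 * q_l / ((1 - rho) * il + 2 * (1 + rho) * kappa * dil)
    r = np.linalg.norm(points, axis=1)
    ct = np.clip(points[:, 2] / np.maximum(r, 1e-12), -1, 1)
    out = np.zeros(len(points))
    for l in ls:
        out += c_l[l] * spherical_in(l, k * r) * eval_legendre(l, ct)
    return out


class TestVoxelToMesh:
    def test_mesh_volume_matches_voxel_volume(self, default_head):
        model = voxel_to_mesh(default_head, layout=None, mesh_spacing=2.0)
        h2 = default_head.downsample_majority(2)
        vox_vol = h2.head_mask().sum() * h2.voxel_volume
        assert model.tet_volumes().sum() == pytest.approx(vox_vol, rel=1e-12)

    def test_per_tissue_volume_within_5pct(self, default_head):
        mesh = voxel_to_mesh(default_head, layout=None)
        mesh_vols = mesh.volume_by_label()
        vox_vols = default_head.tissue_volumes()
        for t, v in vox_vols.items():
            if v > 0:
                assert mesh_vols[int(t)] == pytest.approx(v, rel=0.05)

    def test_optode_refinement_halves_edges_near_patches(self, slab):
        head, _, layout = slab
        coarse = voxel_to_mesh(head, layout, refine_optodes=False)
        fine = voxel_to_mesh(head, layout, refine_optodes=True,
                             refine_radius=4.0)
        c_src = layout.source_positions[0]

        def mean_edge(model):
            cents = model.mesh.nodes[model.mesh.tets].mean(axis=1)
            near = np.linalg.norm(cents - c_src, axis=1) < 3.0
            return model.mesh.edge_lengths(near).mean()

        assert mean_edge(fine) == pytest.approx(0.5 * mean_edge(coarse),
                                                rel=0.05)


class TestPatches:
    def test_patch_areas_positive_and_disjoint(self, small_ball):
        model, _ = small_ball
        a_src = model.patch_area(model.source_patches[0])
        a_det = model.patch_area(model.detector_patches[0])
        assert a_src > 0 and a_det > 0
        assert np.intersect1d(model.source_patches[0],
                              model.detector_patches[0]).size == 0

    def test_overlapping_optodes_rejected(self):
        mesh = ball_mesh(20.0, n_layers=8, subdiv=3, label=int(Tissue.GM))
        lay = OptodeLayout(np.array([[0.0, 0.0, 20.0]]),
                           np.array([[0.5, 0.0, 20.0]]),
                           launch_target=np.zeros(3))
        with pytest.raises(ValueError):
            tag_patches(mesh, lay)


class TestForwardSolve:
    def test_zero_frequency_solution_real(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.0)
        phi = s.solve_source(0)
        assert np.abs(phi.imag).max() < 1e-10 * np.abs(phi.real).max()

    def test_linearity_in_source_strength(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        phi = s.solve_source(0)
        b = s._patch_load(model.source_patches[0], normalize_area=True)
        rhs = 2.0 * (2.0 / (1.0 + s.rho)) * b
        phi2 = s.lu.solve(rhs.astype(complex))
        assert np.allclose(phi2, 2.0 * phi, rtol=1e-12)

    def test_against_exact_series_solution(self):
        """FEM fluence matches the closed-form Legendre-Bessel series on
        the homogeneous ball away from the source (CW system solved
        iteratively on a fine mesh)."""
        mesh = ball_mesh(30.0, n_layers=16, subdiv=4, label=int(Tissue.GM))
        optics = OpticalTable({Tissue.GM: TissueOpticalProperties(
            Tissue.GM, 0.01, 10.0, 0.9, 1.4)})
        th = 0.9
        lay = OptodeLayout(np.array([[0.0, 0.0, 30.0]]),
                           np.array([[30 * np.sin(th), 0.0, 30 * np.cos(th)]]),
                           launch_target=np.zeros(3))
        model = tag_patches(mesh, lay)
        s = DASolver(model, optics, f=0.0, method="cg")
        phi = s.solve_source(0).real
        pts = mesh.nodes
        dist_src = np.linalg.norm(pts - np.array([0.0, 0.0, 30.0]), axis=1)
        sel = dist_src > 8.0
        exact = ball_series_solution(pts[sel], 30.0, 0.01, 1.0, s.rho)
        rel = np.abs(phi[sel] - exact) / np.abs(exact)
        assert np.median(rel) < 0.03

    def test_rho_uses_tissue_index(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        assert s.rho == pytest.approx(effective_reflection(1.4, 1.0))


class TestBoundaryMeasurement:
    def test_rho_one_gives_zero_measurement(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1, rho=1.0 - 1e-15)
        phi = np.ones(model.mesh.n_nodes, complex)
        M = s.boundary_measurement(phi, 0)
        assert abs(M) < 1e-12

    def test_constant_field_integrates_to_patch_area(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        phi = np.ones(model.mesh.n_nodes, complex)
        S = model.patch_area(model.detector_patches[0])
        expected = 0.5 * (1 - s.rho) / (1 + s.rho) * S
        assert s.boundary_measurement(phi, 0) == pytest.approx(expected)

    def test_reciprocity(self):
        """Swapping source and detector roles yields the same measurement
        (symmetric sesquilinear form), up to the area normalization of
        the source model."""
        mesh = ball_mesh(20.0, n_layers=8, subdiv=3, label=int(Tissue.GM))
        optics = OpticalTable({Tissue.GM: TissueOpticalProperties(
            Tissue.GM, 0.01, 10.0, 0.9, 1.4)})
        p1 = np.array([0.0, 0.0, 20.0])
        th = 1.1
        p2 = np.array([20 * np.sin(th), 0.0, 20 * np.cos(th)])
        lay12 = OptodeLayout(p1[None], p2[None], launch_target=np.zeros(3))
        lay21 = OptodeLayout(p2[None], p1[None], launch_target=np.zeros(3))
        m12 = tag_patches(mesh, lay12)
        m21 = tag_patches(mesh, lay21)
        s12 = DASolver(m12, optics, f=0.1)
        s21 = DASolver(m21, optics, f=0.1)
        M12 = s12.boundary_measurement(s12.solve_source(0), 0)
        M21 = s21.boundary_measurement(s21.solve_source(0), 0)
        # normalize out the source patch areas (Q is area-normalized)
        a12 = m12.patch_area(m12.source_patches[0])
        a21 = m21.patch_area(m21.source_patches[0])
        assert M12 * a12 == pytest.approx(M21 * a21, rel=1e-6)


class TestAdjoint:
    def test_adjoint_equals_forward_for_same_patch(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        adj = s.solve_adjoint(0)
        # forward with the detector patch as source, un-normalized
        b = s._patch_load(model.detector_patches[0], normalize_area=False)
        fwd = s.lu.solve(((2.0 / (1.0 + s.rho)) * b).astype(complex))
        assert np.allclose(adj, fwd)

    def test_zero_frequency_adjoint_real(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.0)
        adj = s.solve_adjoint(0)
        assert np.abs(adj.imag).max() < 1e-10 * np.abs(adj.real).max()

    def test_single_factorization_for_all_rhs(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        s.solve_source(0)
        s.solve_adjoint(0)
        s.solve_source(0)
        assert s.n_factorizations == 1


class TestFrechet:
    def test_zero_direction_gives_zero(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        phi = s.solve_source(0)
        adj = s.solve_adjoint(0)
        assert s.frechet_absorption(phi, adj, np.zeros(model.mesh.n_tets)) == 0

    def test_linearity_in_direction(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        phi = s.solve_source(0)
        adj = s.solve_adjoint(0)
        rng = np.random.default_rng(3)
        z1 = rng.random(model.mesh.n_tets)
        z2 = rng.random(model.mesh.n_tets)
        d1 = s.frechet_absorption(phi, adj, z1)
        d2 = s.frechet_absorption(phi, adj, z2)
        d12 = s.frechet_absorption(phi, adj, z1 + z2)
        assert d12 == pytest.approx(d1 + d2, rel=1e-12)

    def test_matches_perturb_and_resolve(self, small_ball):
        """Fréchet derivative vs exact re-solve with mu_a +/- delta in
        single elements: relative error well under 1e-3."""
        model, optics = small_ball
        s = DASolver(model, optics, f=0.1)
        phi = s.solve_source(0)
        adj = s.solve_adjoint(0)
        dM = s.frechet_absorption(phi, adj)
        rng = np.random.default_rng(1)
        cand = np.where(np.abs(dM) > np.percentile(np.abs(dM), 60))[0]
        delta = 1e-5
        for e in rng.choice(cand, 8, replace=False):
            Mp = s.boundary_measurement(
                s.resolve_with_perturbation(e, +delta, phi), 0)
            Mm = s.boundary_measurement(
                s.resolve_with_perturbation(e, -delta, phi), 0)
            fd = (Mp - Mm) / (2 * delta)
            assert abs(fd - dM[e]) / abs(dM[e]) < 1e-3


class TestDAJacobianRows:
    def test_cw_phase_rows_vanish(self, small_ball):
        from fdot.da import da_jacobian

        model, optics = small_ball
        J = da_jacobian(model, optics, f=0.0, mask=np.ones(1, bool))
        assert np.abs(J.phase).max() < 1e-12 * max(np.abs(J.lnA).max(), 1e-300)

    def test_cw_lnA_rows_equal_re_ratio(self, small_ball):
        model, optics = small_ball
        s = DASolver(model, optics, f=0.0)
        phi = s.solve_source(0)
        adj = s.solve_adjoint(0)
        M = s.boundary_measurement(phi, 0)
        dM = s.frechet_absorption(phi, adj)
        from fdot.mc_jacobian import logamp_phase_jacobian
        d_lnA, _ = logamp_phase_jacobian(M.real, -M.imag, dM.real, -dM.imag)
        assert np.allclose(d_lnA, dM.real / M.real)


class TestMeasurementVectorDA:
    def test_mesh_refinement_cauchy_convergence(self):
        """M_jk on the homogeneous ball approaches a limit under mesh
        refinement (shrinking Cauchy differences)."""
        optics = OpticalTable({Tissue.GM: TissueOpticalProperties(
            Tissue.GM, 0.01, 10.0, 0.9, 1.4)})
        th = 0.9
        lay = OptodeLayout(np.array([[0.0, 0.0, 30.0]]),
                           np.array([[30 * np.sin(th), 0.0, 30 * np.cos(th)]]),
                           launch_target=np.zeros(3))
        Ms = []
        for subdiv, layers in [(2, 5), (3, 10), (4, 16)]:
            mesh = ball_mesh(30.0, n_layers=layers, subdiv=subdiv,
                             label=int(Tissue.GM))
            model = tag_patches(mesh, lay)
            s = DASolver(model, optics, f=0.0, method="cg")
            vec = assemble_measurement_vector_da(model, optics, f=0.0,
                                                 solver=s)
            Ms.append(vec.log_amplitude(masked=False)[0])
        assert abs(Ms[2] - Ms[1]) < abs(Ms[1] - Ms[0])
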