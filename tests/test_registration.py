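import numpy as np
import pytest

from fdot.geometry import CranialPointSet, VoxelHeadModel
from fdot.optical import Tissue
from fdot.phantom import HeadParams, cranial_points, generate_head
from fdot.registration import (AffineTransform, RegistrationError, affine_fit,
                               fill_reference_shell, probe_region_scaling,
                               resample_to_reference)


@pytest.fixture(scope="module")
def ref_points(default_head):
    return cranial_points(default_head)


def transformed_points(pts: CranialPointSet, T: AffineTransform) -> CranialPointSet:
    return CranialPointSet(T.apply(pts.surface_points),
                           {k: T.apply(v)[0] for k, v in pts.landmarks.items()})


class TestAffineFit:
    def test_identity_for_identical_points(self, ref_points):
        T, rep = affine_fit(ref_points, ref_points)
        assert np.allclose(T.matrix, AffineTransform.identity().matrix, atol=1e-9)
        assert rep.RE < 1e-18

    def test_recovers_known_affine(self, ref_points):
        rng = np.random.default_rng(0)
        B = np.eye(3) + 0.08 * rng.standard_normal((3, 3))
        assert np.linalg.det(B) > 0
        t = rng.uniform(-5, 5, 3)
        T_true = AffineTransform(np.hstack([B, t[:, None]]))
        subject = transformed_points(ref_points, T_true.inverse())
        T, rep = affine_fit(subject, ref_points)
        recovered = transformed_points(subject, T)
        assert np.allclose(recovered.all_points(), ref_points.all_points(),
                           atol=1e-9)
        assert rep.RE < 1e-12  # mm^2

    def test_re_decomposition_identity(self, ref_points):
        rng = np.random.default_rng(1)
        noisy = CranialPointSet(
            ref_points.surface_points + rng.normal(0, 1.5, (249, 3)),
            {k: v + rng.normal(0, 1.5, 3) for k, v in ref_points.landmarks.items()})
        _, rep = affine_fit(noisy, ref_points, gamma1=0.4, gamma2=0.6)
        assert rep.RE == pytest.approx(
            rep.SRE + 0.4 * rep.LRE1 + 0.6 * rep.LRE2, rel=1e-12)
        assert rep.RE <= rep.RE_before  # no worse than Nz-matched identity

    def test_heavier_gamma1_reduces_lre1(self, ref_points):
        """With a conflicting Iz constraint, raising gamma1 trades SRE
        for a smaller landmark error."""
        lm = {k: v.copy() for k, v in ref_points.landmarks.items()}
        lm["Iz"] = lm["Iz"] + np.array([0.0, -6.0, 3.0])
        conflicted = CranialPointSet(ref_points.surface_points.copy(), lm)
        _, rep_lo = affine_fit(conflicted, ref_points, gamma1=0.45)
        _, rep_hi = affine_fit(conflicted, ref_points, gamma1=0.90)
        assert rep_hi.LRE1 < rep_lo.LRE1

    def test_reflection_rejected(self, ref_points):
        mirror = AffineTransform.identity().matrix.copy()
        mirror[0, 0] = -1.0
        mirrored = CranialPointSet(
            ref_points.surface_points * np.array([-1, 1, 1]),
            {k: v * np.array([-1, 1, 1]) for k, v in ref_points.landmarks.items()})
        with pytest.raises(RegistrationError):
            affine_fit(mirrored, ref_points)


class TestProbeRegionScaling:
    def test_coincident_surfaces_give_unit_scales(self, default_head, ref_points):
        surf = default_head.surface_points()
        nz = ref_points.landmarks["Nz"]
        center = surf[np.argmax(surf[:, 2])]
        T, before, after = probe_region_scaling(surf, surf, center, nz)
        assert np.allclose(np.diag(T.linear), 1.0, atol=1e-9)
        assert after <= before

    def test_recovers_known_anisotropic_scaling(self, default_head, ref_points):
        surf = default_head.surface_points()
        nz = ref_points.landmarks["Nz"]
        scales = np.array([1.1, 0.9, 1.0])
        subject = nz + (surf - nz) * scales
        center = subject[np.argmax(subject[:, 2])]
        T, before, after = probe_region_scaling(subject, surf, center, nz,
                                                radius=60.0)
        rec = np.diag(T.linear)
        assert np.allclose(rec, 1.0 / scales, rtol=0.02)
        assert after <= before

    def test_empty_region_rejected(self, default_head, ref_points):
        surf = default_head.surface_points()
        with pytest.raises(RegistrationError):
            probe_region_scaling(surf, surf, np.array([500.0, 500, 500]),
                                 ref_points.landmarks["Nz"], radius=5.0)


class TestFillShell:
    def test_warped_equals_reference_is_identity(self, default_head):
        filled, rep = fill_reference_shell(default_head, default_head)
        assert rep.accepted
        assert rep.qc_rule1_pass and rep.qc_rule2_pass
        # the reference S&S layer is thicker than the stamped shell, so
        # the fill is the identity: zero voxels changed
        assert np.array_equal(filled.labels, default_head.labels)
        assert sum(rep.voxels_changed.values()) == 0

    def test_wm_protrusion_triggers_rule2(self, default_head):
        warped = VoxelHeadModel(default_head.labels.copy(),
                                default_head.spacing, default_head.origin)
        # push a WM voxel into the top shell (probe region)
        mask = default_head.head_mask()
        top = np.argwhere(mask)
        k = top[np.argmax(top[:, 2])]
        warped.labels[tuple(k)] = int(Tissue.WM)
        _, rep = fill_reference_shell(default_head, warped)
        assert not rep.qc_rule2_pass
        assert not rep.accepted

    def test_foreign_tissue_mismatch_triggers_rule1(self, default_head):
        warped = VoxelHeadModel(default_head.labels.copy(),
                                default_head.spacing, default_head.origin)
        # GM sticking out of the reference head just above the vertex:
        # a rule-(1) violation
        mask = default_head.head_mask()
        top = np.argwhere(mask)
        k = top[np.argmax(top[:, 2])] + np.array([0, 0, 1])
        warped.labels[tuple(k)] = int(Tissue.GM)
        _, rep = fill_reference_shell(default_head, warped)
        assert not rep.qc_rule1_pass

    def test_exterior_bumps_cut_and_shared_boundary(self, default_head):
        rng = np.random.default_rng(2)
        warped = VoxelHeadModel(default_head.labels.copy(),
                                default_head.spacing, default_head.origin)
        mask = default_head.head_mask()
        top = np.argwhere(mask)
        k = top[np.argmax(top[:, 2])] + np.array([0, 0, 1])
        warped.labels[tuple(k)] = int(Tissue.SCALP_SKULL)  # allowed bump
        filled, rep = fill_reference_shell(default_head, warped)
        assert rep.qc_rule1_pass
        assert np.array_equal(filled.head_mask(), default_head.head_mask())


class TestResample:
    def test_label_set_preserved(self, default_head):
        T = AffineTransform(np.hstack([np.eye(3) * 1.03,
                                       np.array([[1.0], [0.5], [-0.7]])]))
        warped = resample_to_reference(default_head, T, default_head)
        assert set(np.unique(warped.labels)) <= set(np.unique(default_head.labels))

    def test_identity_resample_is_exact(self, default_head):
        warped = resample_to_reference(default_head, AffineTransform.identity(),
                                       default_head)
        assert np.array_equal(warped.labels, default_head.labels)


def test_end_to_end_registration_and_fill(default_head):
    """A mildly deformed subject registers back into the reference shell
    and the result shares the reference exterior bit-exactly."""
    ref_pts = cranial_points(default_head)
    T_def = AffineTransform(np.hstack([np.diag([1.05, 0.97, 1.02]),
                                       np.array([[2.0], [-1.0], [0.5]])]))
    subject = resample_to_reference(default_head, T_def, VoxelHeadModel(
        np.zeros((90, 90, 80), np.int16), default_head.spacing,
        default_head.origin - 5.0))
    subj_pts = cranial_points(subject)
    T, rep = affine_fit(subj_pts, ref_pts)
    warped = resample_to_reference(subject, T, default_head)
    filled, fill_rep = fill_reference_shell(default_head, warped)
    assert np.array_equal(filled.head_mask(), default_head.head_mask())
    assert rep.rmse_after < rep.rmse_before
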