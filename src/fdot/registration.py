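"""Linear atlas-to-reference head registration with shell filling and QC.

The registration makes every atlas anatomy share the reference model's
exact exterior (and therefore identical optode positions) in three
steps:

1. an affine transform (12 unknowns) minimizing the registration error

       RE = SRE + gamma1 * LRE1 + gamma2 * LRE2,

   where SRE is the mean squared distance over all 254 cranial points
   (249 grid positions + 5 landmarks), LRE1 over {Iz, Nz} and LRE2 over
   {LPA, RPA}.  The transform acts about the nasion after the subject's
   Nz is matched to the reference Nz; the stacked least-squares system
   carries diagonal weights 1/sqrt(#observations per term) times
   sqrt(gamma).  Reflections (negative determinant) are rejected.

2. additional per-axis anisotropic scaling minimizing the distance
   between the subject and reference surfaces in the probe region
   (closest-point pairs), again about the nasion;

3. filling: the warped subject is resampled onto the reference grid
   (nearest label), the reference's 2 mm scalp-and-skull shell is
   stamped on top, exterior bumps are cut, and interior slack is
   relabelled S&S.

Quality control mirrors the study rules: (1) inside the probe region
the warped and reference head masks may differ only in S&S and CSF-1
voxels, with at most 10 mm^3 of CSF-1 difference; (2) no WM voxels may
be removed from the probe region by the cut.  Subjects failing either
rule are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import CranialPointSet, VoxelHeadModel
from .optical import Tissue

__all__ = ["AffineTransform", "RegistrationReport", "RegistrationError",
           "affine_fit", "probe_region_scaling", "resample_to_reference",
           "fill_reference_shell"]


class RegistrationError(ValueError):
    pass


@dataclass
class AffineTransform:
    """World-coordinate affine map x -> B x + t (mm)."""

    matrix: np.ndarray  # (3, 4): [B | t]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 4)
        if np.linalg.det(self.matrix[:, :3]) <= 0:
            raise RegistrationError("affine transform is not orientation-preserving")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        B = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform(np.hstack([B, t[:, None]]))

    def inverse(self) -> "AffineTransform":
        Bi = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([Bi, (-Bi @ self.translation)[:, None]]))

    def save(self, path) -> None:
        np.savetxt(path, self.matrix)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))


@dataclass
class RegistrationReport:
    """Registration-error bookkeeping and QC outcome."""

    RE: float = np.nan          # mm^2
    SRE: float = np.nan
    LRE1: float = np.nan
    LRE2: float = np.nan
    gamma1: float = np.nan
    gamma2: float = np.nan
    RE_before: float = np.nan
    rmse_before: float = np.nan  # mm, over the 254 cranial points
    rmse_after: float = np.nan
    probe_rmse_before: float = np.nan
    probe_rmse_after: float = np.nan
    qc_rule1_pass: bool | None = None
    qc_rule2_pass: bool | None = None
    accepted: bool | None = None
    voxels_changed: dict = field(default_factory=dict)  # tissue -> mm^3
    csf1_mismatch_mm3: float = np.nan
    gm_lost_mm3: float = np.nan


def _re_terms(subj: np.ndarray, ref: np.ndarray, gamma1: float, gamma2: float):
    """(RE, SRE, LRE1, LRE2) of stacked point arrays ordered like
    CranialPointSet.all_points() (surface..., Iz, Nz, LPA, RPA, Cz)."""
    d2 = ((subj - ref) ** 2).sum(axis=1)
    sre = d2.mean()
    n = len(d2)
    lre1 = d2[[n - 5, n - 4]].mean()   # Iz, Nz
    lre2 = d2[[n - 3, n - 2]].mean()   # LPA, RPA
    return sre + gamma1 * lre1 + gamma2 * lre2, sre, lre1, lre2


def affine_fit(subject: CranialPointSet, reference: CranialPointSet,
               gamma1: float = 0.45, gamma2: float = 0.55
               ) -> tuple[AffineTransform, RegistrationReport]:
    """Weighted linear least-squares affine registration of the cranial
    points, about the nasion."""
    if gamma1 < 0 or gamma2 < 0:
        raise ValueError("gamma weights must be nonnegative")
    ps = subject.all_points()
    pr = reference.all_points()
    nz_s = subject.landmarks["Nz"]
    nz_r = reference.landmarks["Nz"]
    shift = nz_r - nz_s
    # coordinates relative to the reference nasion, subject Nz pre-matched
    qs = ps + shift - nz_r
    qr = pr - nz_r

    rep = RegistrationReport(gamma1=gamma1, gamma2=gamma2)
    rep.RE_before, *_ = _re_terms(qs, qr, gamma1, gamma2)
    rep.rmse_before = float(np.sqrt(((qs - qr) ** 2).sum(1).mean()))

    n = len(qs)
    # stacked rows: SRE block (all 254 points), LRE1 (Iz, Nz), LRE2 (LPA, RPA)
    blocks = [(np.arange(n), np.sqrt(1.0 / n)),
              (np.array([n - 5, n - 4]), np.sqrt(gamma1 / 2.0)),
              (np.array([n - 3, n - 2]), np.sqrt(gamma2 / 2.0))]
    rows_A, rows_b = [], []
    for idx, w in blocks:
        P = np.hstack([qs[idx], np.ones((len(idx), 1))])  # (k, 4)
        Z = np.zeros_like(P)
        A = np.block([[P, Z, Z], [Z, P, Z], [Z, Z, P]])
        rows_A.append(w * A)
        rows_b.append(w * qr[idx].T.reshape(-1))
    A = np.vstack(rows_A)
    b = np.concatenate(rows_b)
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 12:
        raise RegistrationError("degenerate point configuration (rank-deficient)")
    M = sol.reshape(3, 4)

    # full world transform: x -> B(x + shift - nz_r) + t + nz_r
    B = M[:, :3]
    t = M[:, 3]
    full = np.hstack([B, (B @ (shift - nz_r) + t + nz_r)[:, None]])
    transform = AffineTransform(full)  # raises on reflections

    qs_after = transform.apply(ps) - nz_r
    rep.RE, rep.SRE, rep.LRE1, rep.LRE2 = _re_terms(qs_after, qr, gamma1, gamma2)
    rep.rmse_after = float(np.sqrt(((qs_after - qr) ** 2).sum(1).mean()))
    return transform, rep


def probe_region_scaling(subject_surface: np.ndarray,
                         reference_surface: np.ndarray,
                         probe_center: np.ndarray,
                         nasion: np.ndarray,
                         radius: float = 60.0, n_iter: int = 10
                         ) -> tuple[AffineTransform, float, float]:
    """Per-axis scaling (about the nasion) minimizing the closest-point
    distance between the surfaces in the probe region.

    Closest-point pairing and the per-axis least-squares scales are
    iterated (pairings change as the surfaces approach) until the scale
    update is negligible.  Returns (scaling transform, probe RMSE
    before, after)."""
    subject_surface = np.asarray(subject_surface, float)
    sel = np.linalg.norm(subject_surface - probe_center, axis=1) < radius
    if not sel.any():
        raise RegistrationError("empty probe region")
    p0 = subject_surface[sel]
    tree = cKDTree(reference_surface)

    def rmse(pts):
        _, nearest = tree.query(pts)
        q = np.asarray(reference_surface)[nearest]
        return float(np.sqrt(((pts - q) ** 2).sum(1).mean())), q

    rmse_before, _ = rmse(p0)
    total = np.ones(3)
    p = p0
    for _ in range(max(1, n_iter)):
        _, q = rmse(p)
        pc = p - nasion
        qc = q - nasion
        denom = (pc ** 2).sum(axis=0)
        s = np.where(denom > 0, (pc * qc).sum(axis=0) / np.maximum(denom, 1e-300), 1.0)
        total = total * s
        p = nasion + (p - nasion) * s
        if np.abs(s - 1.0).max() < 1e-6:
            break
    T = AffineTransform(np.hstack([np.diag(total),
                                   (nasion - total * nasion)[:, None]]))
    rmse_after, _ = rmse(p)
    return T, rmse_before, rmse_after


def resample_to_reference(subject: VoxelHeadModel, transform: AffineTransform,
                          reference: VoxelHeadModel) -> VoxelHeadModel:
    """Warp the subject labels onto the reference voxel grid with
    nearest-label sampling (no partial-volume labels; the label set is
    preserved)."""
    inv = transform.inverse()
    idx = np.indices(reference.shape).reshape(3, -1).T
    world = reference.index_to_world(idx)
    src = inv.apply(world)
    sidx = np.round(subject.world_to_index(src)).astype(int)
    valid = np.all((sidx >= 0) & (sidx < np.array(subject.shape)), axis=1)
    out = np.zeros(len(idx), dtype=subject.labels.dtype)
    out[valid] = subject.labels[sidx[valid, 0], sidx[valid, 1], sidx[valid, 2]]
    return VoxelHeadModel(out.reshape(reference.shape), reference.spacing,
                          reference.origin.copy())


def _shell_mask(reference: VoxelHeadModel, thickness: float) -> np.ndarray:
    mask = np.pad(reference.head_mask(), 1)
    d_out = ndimage.distance_transform_edt(mask, sampling=reference.spacing)
    shell = mask & (d_out <= thickness + 1e-9)
    return shell[1:-1, 1:-1, 1:-1]


def fill_reference_shell(reference: VoxelHeadModel, warped: VoxelHeadModel,
                         shell_thickness: float = 2.0,
                         probe_region: np.ndarray | None = None,
                         csf1_tol_mm3: float = 10.0
                         ) -> tuple[VoxelHeadModel, RegistrationReport]:
    """Stamp the reference S&S shell over the warped model's interior.

    ``warped`` must already live on the reference grid (see
    :func:`resample_to_reference`).  ``probe_region`` is a boolean voxel
    mask on the reference grid (default: everywhere).  A report carries
    the QC outcome; a rejected subject keeps ``accepted=False`` with the
    failing rule flagged."""
    if warped.shape != reference.shape:
        raise ValueError("warped model is not on the reference grid")
    vv = reference.voxel_volume
    if probe_region is None:
        probe_region = np.ones(reference.shape, bool)
    ref_mask = reference.head_mask()
    warp_mask = warped.head_mask()
    shell = _shell_mask(reference, shell_thickness)

    rep = RegistrationReport()
    # QC rule 1: head-mask differences in the probe region may involve
    # only S&S and CSF-1, with limited CSF-1 volume
    diff = (ref_mask ^ warp_mask) & probe_region
    diff_labels = np.where(ref_mask & diff, reference.labels, warped.labels)[diff]
    allowed = np.isin(diff_labels, [int(Tissue.SCALP_SKULL), int(Tissue.CSF1)])
    csf1_mm3 = float(np.count_nonzero(diff_labels == int(Tissue.CSF1))) * vv
    rep.csf1_mismatch_mm3 = csf1_mm3
    rep.qc_rule1_pass = bool(allowed.all() and csf1_mm3 <= csf1_tol_mm3)

    # QC rule 2: cutting must not remove WM from the probe region
    cut = (~ref_mask | shell) & probe_region
    rep.qc_rule2_pass = not bool(np.any(cut & (warped.labels == int(Tissue.WM))))

    rep.accepted = rep.qc_rule1_pass and rep.qc_rule2_pass

    out = warped.labels.copy()
    out[~ref_mask] = 0                              # cut exterior bumps
    out[shell] = int(Tissue.SCALP_SKULL)            # stamp the reference shell
    hole = ref_mask & ~shell & (out == 0)           # interior slack -> S&S
    out[hole] = int(Tissue.SCALP_SKULL)

    changed = out != warped.labels
    for t in Tissue:
        if t is Tissue.BACKGROUND:
            continue
        rep.voxels_changed[t.name] = float(
            np.count_nonzero(changed & (warped.labels == int(t)))) * vv
    rep.gm_lost_mm3 = float(np.count_nonzero(
        changed & (warped.labels == int(Tissue.GM)) & probe_region)) * vv

    return VoxelHeadModel(out, reference.spacing, reference.origin.copy()), rep
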