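"""Frequency-domain diffusion approximation with P1 finite elements.

Forward model (one source k):

    -div(kappa grad Phi_k) + (i omega / c + mu_a) Phi_k = 0      in Omega,
    (1 - rho) Phi_k + 2 (1 + rho) nu . kappa grad Phi_k = 4 Q_k  on dOmega,

with kappa = 1 / (3 (mu_a + mu_s')), omega = 2 pi f, and rho the
effective reflection coefficient of the refractive-index mismatch at the
boundary.  Q_k is the characteristic function of the k-th source patch
divided by its area (a homogeneous diffuse emitter of unit strength);
the sensor measurement is

    M_jk = 1/2 (1 - rho) / (1 + rho) * int P_j Phi_k dS,

with P_j the characteristic function of the j-th sensor patch.

The adjoint problem swaps the boundary source for 4 P_j and shares the
(complex symmetric) system operator, so one sparse factorization serves
all n_s + n_d right-hand sides.  The Fréchet derivative of M_jk with
respect to the absorption in a direction zeta (supported on whole
elements) is

    (D M_jk) zeta = 1/4 (1 - rho) *
        int zeta ( grad Phi_k . grad Phi*_j / (3 (mu_a + mu_s')^2)
                   - Phi_k Phi*_j ) dx,

where the first term carries the dependence of kappa on mu_a.  This
expression is exact for the *discrete* P1 system as well, which is what
makes the finite-difference validation tight.

Sign convention: the measured phase is the phase *delay* of the photon
density wave (positive, growing with distance), so the complex DA
measurement is conjugated when converted to (X, Y, ln A, phi) — this
matches the Monte Carlo convention X = sum w cos(2 pi f t), Y = + sum w
sin(2 pi f t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .fem import (boundary_load_vector, boundary_mass_matrix, mass_matrix,
                  p1_gradients, stiffness_matrix, triangle_areas)
from .geometry import OptodeLayout, VoxelHeadModel
from .measurement import DEFAULT_SDS_MAX, MeasurementVector
from .mc_jacobian import JacobianMatrix, logamp_phase_jacobian
from .mesh import TetMesh, voxel_to_tetmesh
from .optical import C_VACUUM, OpticalTable, effective_reflection

__all__ = ["TetMeshModel", "DASolver", "voxel_to_mesh",
           "assemble_measurement_vector_da", "da_jacobian"]


@dataclass
class TetMeshModel:
    """Tet mesh with tagged optode patches on its boundary."""

    mesh: TetMesh
    layout: OptodeLayout
    source_patches: list[np.ndarray] = field(default_factory=list)
    detector_patches: list[np.ndarray] = field(default_factory=list)

    def patch_area(self, tris_idx: np.ndarray) -> float:
        return float(triangle_areas(self.mesh.nodes, self.mesh.boundary_tris[tris_idx]).sum())


def tag_patches(mesh: TetMesh, layout: OptodeLayout) -> TetMeshModel:
    """Assign boundary facets to optode patches: a facet belongs to the
    patch whose centre lies within the patch radius of its centroid
    (nearest facet as fallback so every patch has positive area).
    Overlapping source/detector patches raise."""
    layout.validate()  # optode disks must not overlap geometrically
    cents = mesh.boundary_centroids()
    model = TetMeshModel(mesh, layout)
    owner = np.full(len(cents), -1, int)
    centers = np.vstack([layout.source_positions, layout.detector_positions])
    for c_i, c in enumerate(centers):
        d = np.linalg.norm(cents - c, axis=1)
        sel = np.where(d <= layout.patch_radius)[0]
        if len(sel) == 0:
            sel = np.array([int(np.argmin(d))])
        if np.any(owner[sel] >= 0):
            raise ValueError("optode patches overlap on the boundary mesh")
        owner[sel] = c_i
        if c_i < layout.n_s:
            model.source_patches.append(sel)
        else:
            model.detector_patches.append(sel)
    return model


def voxel_to_mesh(head: VoxelHeadModel, layout: OptodeLayout | None = None,
                  mesh_spacing: float | None = None,
                  refine_optodes: bool = False,
                  refine_radius: float = 6.0) -> TetMeshModel | TetMesh:
    """Labelled tet mesh from the voxel model, optionally downsampled to
    ``mesh_spacing`` (majority label) and refined near the optode
    patches.  Per-tissue volumes follow the (possibly downsampled) voxel
    volumes exactly because the tetrahedra tile the voxels."""
    h = head
    if mesh_spacing is not None and mesh_spacing > head.spacing:
        factor = int(round(mesh_spacing / head.spacing))
        h = head.downsample_majority(factor)
    refine = None
    if refine_optodes and layout is not None:
        centers = np.vstack([layout.source_positions, layout.detector_positions])
        idx = np.indices(h.shape).reshape(3, -1).T
        cents = h.index_to_world(idx)
        near = np.zeros(len(cents), bool)
        for c in centers:
            near |= np.linalg.norm(cents - c, axis=1) < refine_radius
        refine = near.reshape(h.shape)
    mesh = voxel_to_tetmesh(h.labels, h.spacing, h.origin, refine_mask=refine)
    if layout is None:
        return mesh
    return tag_patches(mesh, layout)


class DASolver:
    """Assembled FD diffusion system with a reusable factorization."""

    def __init__(self, model: TetMeshModel, optics: OpticalTable,
                 f: float = 0.1, rho: float | None = None,
                 n_exterior: float = 1.0, method: str = "direct"):
        mesh = model.mesh
        self.model = model
        self.f = float(f)
        self.omega = 2.0 * np.pi * self.f  # rad / ns

        mu_a_tab, mu_s_tab, g_tab, n_tab = optics.as_arrays(int(mesh.labels.max()))
        lab = mesh.labels
        self.mu_a = mu_a_tab[lab]
        self.mu_sp = (1.0 - g_tab[lab]) * mu_s_tab[lab]
        self.kappa = 1.0 / (3.0 * (self.mu_a + self.mu_sp))
        self.c_med = C_VACUUM / n_tab[lab]
        if rho is None:
            n_int = float(np.max(n_tab[lab]))
            rho = effective_reflection(n_int, n_exterior) if n_int > n_exterior else 0.0
        self.rho = float(rho)

        gv = p1_gradients(mesh.nodes, mesh.tets)
        self._grads, self._vols = gv
        K = stiffness_matrix(mesh.nodes, mesh.tets, self.kappa, grads_vols=gv)
        M_r = mass_matrix(mesh.nodes, mesh.tets, self.mu_a, grads_vols=gv)
        M_i = mass_matrix(mesh.nodes, mesh.tets, self.omega / self.c_med, grads_vols=gv)
        robin = (1.0 - self.rho) / (2.0 * (1.0 + self.rho))
        B = boundary_mass_matrix(mesh.nodes, mesh.boundary_tris, robin)
        self.system = (K + M_r + B).astype(complex) + 1j * M_i
        self._lu = None
        self.n_factorizations = 0
        if method not in ("direct", "cg"):
            raise ValueError("method must be 'direct' or 'cg'")
        if method == "cg" and self.omega != 0.0:
            raise ValueError("the cg path applies to the real (f = 0) system")
        self.method = method

    # -- linear algebra ----------------------------------------------------

    @property
    def lu(self):
        if self._lu is None:
            self._lu = splu(self.system.tocsc())
            self.n_factorizations += 1
        return self._lu

    def _linsolve(self, rhs: np.ndarray) -> np.ndarray:
        if self.method == "cg":
            from scipy.sparse.linalg import LinearOperator, cg

            A = self.system.real.tocsr()
            d = A.diagonal()
            x, info = cg(A, rhs.real, rtol=1e-12, atol=0.0, maxiter=20000,
                         M=LinearOperator(A.shape, matvec=lambda v: v / d))
            if info != 0:
                return self.lu.solve(rhs.astype(complex))
            return x.astype(complex)
        return self.lu.solve(rhs.astype(complex))

    def _patch_load(self, tris_idx: np.ndarray, normalize_area: bool) -> np.ndarray:
        mesh = self.model.mesh
        tris = mesh.boundary_tris[tris_idx]
        coeff = 1.0
        if normalize_area:
            coeff = 1.0 / triangle_areas(mesh.nodes, tris).sum()
        return boundary_load_vector(mesh.nodes, tris, coeff, mesh.n_nodes)

    def solve_source(self, k: int) -> np.ndarray:
        """Forward fluence Phi_k (complex nodal values)."""
        b = self._patch_load(self.model.source_patches[k], normalize_area=True)
        rhs = (2.0 / (1.0 + self.rho)) * b
        return self._linsolve(rhs)

    def solve_adjoint(self, j: int) -> np.ndarray:
        """Adjoint fluence Phi*_j (detector patch as diffuse source)."""
        b = self._patch_load(self.model.detector_patches[j], normalize_area=False)
        rhs = (2.0 / (1.0 + self.rho)) * b
        return self._linsolve(rhs)

    def resolve_with_perturbation(self, element: int, delta: float,
                                  base_solution: np.ndarray) -> np.ndarray:
        """Exact solution of the system with mu_a perturbed by ``delta``
        in one element ("perturb and re-solve").

        The perturbation changes only the 4x4 element block (element
        mass scaled by delta plus element stiffness scaled by the exact
        kappa change), so the perturbed system is the base system plus a
        rank-4 update; the solution follows from the base factorization
        via the Woodbury identity without refactorizing.
        """
        mesh = self.model.mesh
        nodes4 = mesh.tets[element]
        g = self._grads[element]
        vol = self._vols[element]
        mu_e = self.mu_a[element]
        d_kappa = 1.0 / (3.0 * (mu_e + delta + self.mu_sp[element])) - self.kappa[element]
        Ke = (g @ g.T) * vol
        Me = vol / 20.0 * (np.ones((4, 4)) + np.eye(4))
        C = (d_kappa * Ke + delta * Me).astype(complex)

        P = np.zeros((self.system.shape[0], 4), complex)
        P[nodes4, np.arange(4)] = 1.0
        W = self.lu.solve(P)                      # K^-1 P
        S = np.linalg.inv(C) + W[nodes4, :]       # C^-1 + P^T K^-1 P
        corr = W @ np.linalg.solve(S, base_solution[nodes4])
        return base_solution - corr

    # -- measurements ------------------------------------------------------

    def boundary_measurement(self, field: np.ndarray, j: int) -> complex:
        """M_jk = 1/2 (1-rho)/(1+rho) int P_j Phi dS (facet quadrature)."""
        patch = self.model.detector_patches[j]
        for sp in self.model.source_patches:
            if np.intersect1d(patch, sp).size:
                raise ValueError("detector patch overlaps a source patch")
        b = self._patch_load(patch, normalize_area=False)
        return complex(0.5 * (1.0 - self.rho) / (1.0 + self.rho) * (b @ field))

    def frechet_absorption(self, forward: np.ndarray, adjoint: np.ndarray,
                           zeta: np.ndarray | None = None) -> np.ndarray | complex:
        """Fréchet derivative of M_jk w.r.t. element absorptions.

        With ``zeta=None`` returns the (n_tets,) array of per-element
        derivatives (zeta = indicator of each element); otherwise the
        derivative in the direction of the per-element vector ``zeta``.
        """
        mesh = self.model.mesh
        tets = mesh.tets
        gph_f = np.einsum("mid,mi->md", self._grads, forward[tets])
        gph_a = np.einsum("mid,mi->md", self._grads, adjoint[tets])
        grad_term = np.einsum("md,md->m", gph_f, gph_a) * self._vols \
            / (3.0 * (self.mu_a + self.mu_sp) ** 2)
        pf = forward[tets]
        pa = adjoint[tets]
        # exact integral of the product of two P1 fields over a tet
        mass_term = (np.einsum("mi,mi->m", pf, pa) + pf.sum(1) * pa.sum(1)) \
            * self._vols / 20.0
        d = 0.25 * (1.0 - self.rho) * (grad_term - mass_term)
        if zeta is None:
            return d
        return complex((d * np.asarray(zeta)).sum())


def assemble_measurement_vector_da(model: TetMeshModel, optics: OpticalTable,
                                   f: float = 0.1,
                                   sds_max: float = DEFAULT_SDS_MAX,
                                   solver: DASolver | None = None,
                                   return_solver: bool = False):
    """Solve all sources and evaluate all sensor integrals; source-major
    MeasurementVector sharing the MC schema (phase = phase delay)."""
    s = solver or DASolver(model, optics, f=f)
    n_s, n_d = model.layout.n_s, model.layout.n_d
    X = np.zeros(n_s * n_d)
    Y = np.zeros(n_s * n_d)
    for k in range(n_s):
        phi = s.solve_source(k)
        for j in range(n_d):
            M = s.boundary_measurement(phi, j)
            X[k * n_d + j] = M.real
            Y[k * n_d + j] = -M.imag  # conjugate: phase delay positive
    vec = MeasurementVector(X, Y, model.layout.sds_matrix().ravel(), n_s, n_d,
                            f=f, n_detected=None, sds_max=sds_max)
    vec.n_detected = None
    return (vec, s) if return_solver else vec


def da_jacobian(model: TetMeshModel, optics: OpticalTable, f: float,
                mask: np.ndarray, solver: DASolver | None = None,
                normalize_volume: bool = True) -> JacobianMatrix:
    """Adjoint-method ln A and phase Jacobian over masked-in pairs.

    One factorization serves the n_s forward and n_d adjoint solves; the
    complex Fréchet derivatives are decomposed into real and imaginary
    parts and reduced with the same chain-rule formulas as the MC replay
    Jacobians.  Columns are per-tet; values per absorption change in
    1 mm^3 when ``normalize_volume`` (divide by element volume).
    """
    s = solver or DASolver(model, optics, f=f)
    n_s, n_d = model.layout.n_s, model.layout.n_d
    fwd = [s.solve_source(k) for k in range(n_s)]
    adj = [s.solve_adjoint(j) for j in range(n_d)]
    vols = s.model.mesh.tet_volumes()
    rows_lnA, rows_phi, pairs = [], [], []
    for k in range(n_s):
        for j in range(n_d):
            if not mask[k * n_d + j]:
                continue
            M = s.boundary_measurement(fwd[k], j)
            dM = s.frechet_absorption(fwd[k], adj[j])
            X, Y = M.real, -M.imag
            dX, dY = dM.real, -dM.imag
            d_lnA, d_phi = logamp_phase_jacobian(X, Y, dX, dY)
            if normalize_volume:
                d_lnA = d_lnA / vols
                d_phi = d_phi / vols
            rows_lnA.append(d_lnA)
            rows_phi.append(d_phi)
            pairs.append((k, j))
    return JacobianMatrix(np.array(rows_lnA), np.array(rows_phi),
                          np.array(pairs, int), element_volume=1.0)
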