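"""First-order (P1) tetrahedral finite-element assembly.

Shared by the diffusion-approximation solver and the CSF Laplace split.
All integrals over P1 products are evaluated exactly (polynomial
quadrature): element stiffness from the constant barycentric gradients,
element mass V/20 (2 diag / 1 off-diag), boundary-triangle mass A/12
(2 diag / 1 off-diag).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["p1_gradients", "stiffness_matrix", "mass_matrix",
           "boundary_mass_matrix", "boundary_load_vector"]


def p1_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-element constant gradients of the four barycentric basis
    functions.

    Returns ``(grads, volumes)`` with ``grads`` of shape (m, 4, 3)
    [mm^-1] and ``volumes`` (m,) [mm^3].
    """
    p = nodes[tets]  # (m, 4, 3)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    e3 = p[:, 3] - p[:, 0]
    det = np.einsum("ij,ij->i", e1, np.cross(e2, e3))
    vol = np.abs(det) / 6.0
    # rows of the inverse Jacobian give grad lambda_1..3; lambda_0 = -sum
    c1 = np.cross(e2, e3) / det[:, None]
    c2 = np.cross(e3, e1) / det[:, None]
    c3 = np.cross(e1, e2) / det[:, None]
    g = np.empty((len(tets), 4, 3))
    g[:, 1] = c1
    g[:, 2] = c2
    g[:, 3] = c3
    g[:, 0] = -(c1 + c2 + c3)
    return g, vol


def _assemble(rows, cols, vals, n):
    return sparse.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())),
                             shape=(n, n)).tocsr()


def stiffness_matrix(nodes: np.ndarray, tets: np.ndarray,
                     coeff: np.ndarray | float = 1.0,
                     grads_vols=None) -> sparse.csr_matrix:
    """Assemble ∫ coeff ∇ψ_i · ∇ψ_j dx with element-wise constant coeff."""
    g, vol = p1_gradients(nodes, tets) if grads_vols is None else grads_vols
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (len(tets),))
    ke = np.einsum("mid,mjd->mij", g, g) * (coeff * vol)[:, None, None]
    rows = np.repeat(tets[:, :, None], 4, axis=2)
    cols = np.repeat(tets[:, None, :], 4, axis=1)
    return _assemble(rows, cols, ke, len(nodes))


_MASS_LOCAL = (np.ones((4, 4)) + np.eye(4)) / 20.0
_BMASS_LOCAL = (np.ones((3, 3)) + np.eye(3)) / 12.0


def mass_matrix(nodes: np.ndarray, tets: np.ndarray,
                coeff: np.ndarray | float = 1.0,
                grads_vols=None) -> sparse.csr_matrix:
    """Assemble ∫ coeff ψ_i ψ_j dx with element-wise constant coeff."""
    if grads_vols is None:
        _, vol = p1_gradients(nodes, tets)
    else:
        _, vol = grads_vols
    coeff = np.broadcast_to(np.asarray(coeff), (len(tets),))
    me = _MASS_LOCAL[None, :, :] * (coeff * vol)[:, None, None]
    rows = np.repeat(tets[:, :, None], 4, axis=2)
    cols = np.repeat(tets[:, None, :], 4, axis=1)
    return _assemble(rows, cols, me, len(nodes))


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def boundary_mass_matrix(nodes: np.ndarray, tris: np.ndarray,
                         coeff: np.ndarray | float = 1.0) -> sparse.csr_matrix:
    """Assemble ∫ coeff ψ_i ψ_j dS over boundary triangles."""
    area = triangle_areas(nodes, tris)
    coeff = np.broadcast_to(np.asarray(coeff), (len(tris),))
    me = _BMASS_LOCAL[None, :, :] * (coeff * area)[:, None, None]
    rows = np.repeat(tris[:, :, None], 3, axis=2)
    cols = np.repeat(tris[:, None, :], 3, axis=1)
    return _assemble(rows, cols, me, len(nodes))


def boundary_load_vector(nodes: np.ndarray, tris: np.ndarray,
                         coeff: np.ndarray | float, n_nodes: int) -> np.ndarray:
    """Assemble ∫ coeff ψ_i dS with triangle-wise constant coeff."""
    area = triangle_areas(nodes, tris)
    coeff = np.broadcast_to(np.asarray(coeff), (len(tris),))
    w = (coeff * area / 3.0)
    out = np.zeros(n_nodes)
    np.add.at(out, tris.ravel(), np.repeat(w, 3))
    return out
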