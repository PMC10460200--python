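"""Two-compartment CSF segmentation by a harmonic level set.

The cerebrospinal fluid outside the ventricles is split into a
semidiffusive subarachnoid layer (CSF-1) and clearer sulci CSF (CSF-2)
by solving the Laplace equation on the CSF domain D (the CSF region
minus a thin plate along the longitudinal fissure) with mixed boundary
conditions:

* u = 0 where the CSF touches brain tissue (GM/WM),
* u = 1 where it touches the scalp-and-skull shell or the fissure plate,
* homogeneous Neumann in an ``a``-neighbourhood of junctions where brain
  and skull (or brain and plate) meet, so that the two Dirichlet sets
  never share a node and the problem stays well posed in H^1.

The level set u = theta (default 0.6) of the harmonic solution forms a
smooth interface loosely enclosing the cerebral hemispheres; CSF voxels
above the threshold become CSF-1, the rest (and always the ventricles)
CSF-2.  The split only relabels CSF voxels: total CSF volume is
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .fem import stiffness_matrix
from .geometry import VoxelHeadModel
from .mesh import TetMesh, voxel_to_tetmesh
from .optical import Tissue

__all__ = ["CsfDomain", "HarmonicField", "build_csf_domain",
           "solve_csf_laplace", "threshold_split", "split_csf"]

_PLATE = 99  # sentinel label for the longitudinal-fissure plate


@dataclass
class CsfDomain:
    """Tetrahedral mesh of the CSF region with tagged Dirichlet nodes."""

    mesh: TetMesh
    dirichlet0_nodes: np.ndarray   # u = 0 (brain-adjacent)
    dirichlet1_nodes: np.ndarray   # u = 1 (skull/plate-adjacent)
    neumann_buffer: float          # the junction neighbourhood radius a [mm]
    spacing: float
    origin: np.ndarray
    domain_voxels: np.ndarray      # (n, 3) indices of meshed CSF voxels


@dataclass
class HarmonicField:
    """P1 nodal values of the harmonic level-set function, in [0, 1]."""

    node_values: np.ndarray
    residual: float


def build_csf_domain(head: VoxelHeadModel, a: float = 1.0,
                     with_fissure_plate: bool = True) -> CsfDomain:
    """Mesh the CSF region (minus the fissure plate) and tag its boundary.

    Boundary facets adjacent to GM/WM become Dirichlet-0; facets adjacent
    to S&S, the fissure plate or the exterior become Dirichlet-1.  Nodes
    within distance ``a`` of a 0/1 junction are left unconstrained
    (natural Neumann condition).
    """
    if a < 0:
        raise ValueError("neighbourhood radius a must be nonnegative")
    labels = head.labels
    csf = labels == int(Tissue.CSF1)
    if not csf.any():
        raise ValueError("head contains no CSF outside the ventricles")

    domain_labels = labels.copy()
    if with_fissure_plate:
        # 1-voxel plate at the x midline, from the bottom of the cerebrum up
        brain = (labels == int(Tissue.GM)) | (labels == int(Tissue.WM))
        if brain.any():
            idx = np.argwhere(csf)
            x_mid = int(np.round(idx[:, 0].mean()))
            z_bottom = int(np.argwhere(brain)[:, 2].min())
            plate = np.zeros_like(csf)
            plate[x_mid, :, z_bottom:] = True
            domain_labels[plate & csf] = _PLATE

    include = domain_labels == int(Tissue.CSF1)
    if not include.any():
        raise ValueError("CSF region is empty after removing the fissure plate")
    mesh = voxel_to_tetmesh(domain_labels, head.spacing, head.origin,
                            include_mask=include)

    nb = mesh.boundary_neighbor
    d0_facets = np.isin(nb, [int(Tissue.GM), int(Tissue.WM), int(Tissue.CSF2)])
    d1_facets = np.isin(nb, [int(Tissue.SCALP_SKULL), _PLATE, 0])
    d0_nodes = np.unique(mesh.boundary_tris[d0_facets])
    d1_nodes = np.unique(mesh.boundary_tris[d1_facets])

    junctions = np.intersect1d(d0_nodes, d1_nodes)
    if len(junctions):
        if a == 0:
            raise ValueError(
                "Dirichlet-0 and Dirichlet-1 boundary sets meet and the "
                "Neumann buffer radius a is zero")
        tree = cKDTree(mesh.nodes[junctions])
        near = tree.query_ball_point(mesh.nodes, r=a)
        freed = np.array([len(x) > 0 for x in near])
        d0_nodes = d0_nodes[~freed[d0_nodes]]
        d1_nodes = d1_nodes[~freed[d1_nodes]]
    if np.intersect1d(d0_nodes, d1_nodes).size:
        raise ValueError("Dirichlet sets are not separated after buffering")
    if len(d0_nodes) == 0 and len(d1_nodes) == 0:
        raise ValueError("all-Neumann boundary: Laplace problem is singular")

    return CsfDomain(mesh, d0_nodes, d1_nodes, a, head.spacing,
                     head.origin, np.argwhere(include))


def solve_csf_laplace(domain: CsfDomain) -> HarmonicField:
    """P1 FEM solution of the mixed Dirichlet/Neumann Laplace problem."""
    mesh = domain.mesh
    K = stiffness_matrix(mesh.nodes, mesh.tets)
    n = mesh.n_nodes
    u = np.zeros(n)
    u[domain.dirichlet1_nodes] = 1.0
    fixed = np.zeros(n, bool)
    fixed[domain.dirichlet0_nodes] = True
    fixed[domain.dirichlet1_nodes] = True
    free = ~fixed
    if not free.any():
        return HarmonicField(u, 0.0)
    K_ff = K[free][:, free].tocsr()
    rhs = -K[free][:, fixed] @ u[fixed]
    # SPD after Dirichlet elimination: Jacobi-preconditioned CG, direct fallback
    d = K_ff.diagonal()
    if np.any(d <= 0):
        raise RuntimeError("singular Laplace system (nonpositive diagonal)")
    from scipy.sparse.linalg import LinearOperator, cg
    x, info = cg(K_ff, rhs, rtol=1e-12, atol=0.0, maxiter=10000,
                 M=LinearOperator(K_ff.shape, matvec=lambda v: v / d))
    if info != 0:
        try:
            x = splu(K_ff.tocsc()).solve(rhs)
        except RuntimeError as err:
            raise RuntimeError(f"singular Laplace system: {err}") from err
    u[free] = x
    res = np.linalg.norm(K_ff @ u[free] - rhs) / max(np.linalg.norm(rhs), 1e-300)
    return HarmonicField(u, float(res))


def _voxel_center_values(field: HarmonicField, domain: CsfDomain) -> np.ndarray:
    """Harmonic-field values at the centres of the meshed CSF voxels
    (mean of the eight corner nodes = exact P1 average over the Kuhn
    subdivision's corner values)."""
    mesh = domain.mesh
    h = domain.spacing
    keys_d = np.round((mesh.nodes - domain.origin) / (0.5 * h)).astype(np.int64)
    shape_d = keys_d.max(axis=0) + 1
    key = (keys_d[:, 0] * shape_d[1] + keys_d[:, 1]) * shape_d[2] + keys_d[:, 2]
    order = np.argsort(key)
    key_sorted = key[order]

    vox = domain.domain_voxels
    vals = np.zeros(len(vox))
    corner_off = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])
    for off in corner_off:
        ck = 2 * (vox + off)
        k = (ck[:, 0] * shape_d[1] + ck[:, 1]) * shape_d[2] + ck[:, 2]
        pos = np.searchsorted(key_sorted, k)
        vals += field.node_values[order[pos]]
    return vals / 8.0


def threshold_split(field: HarmonicField, domain: CsfDomain,
                    head: VoxelHeadModel, theta: float = 0.6) -> VoxelHeadModel:
    """Relabel CSF voxels by thresholding the harmonic field.

    Voxels with u > theta become CSF-1 (subarachnoid), u <= theta CSF-2;
    ventricles (already CSF-2) stay CSF-2; non-CSF labels are untouched.
    CSF voxels outside the mesh (the fissure plate) take the value of the
    nearest mesh node.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    out = head.labels.copy()
    vals = _voxel_center_values(field, domain)
    vox = domain.domain_voxels
    csf1 = vals > theta
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = np.where(
        csf1, int(Tissue.CSF1), int(Tissue.CSF2)).astype(out.dtype)

    # CSF voxels not in the meshed domain (fissure plate): nearest node
    all_csf = head.labels == int(Tissue.CSF1)
    meshed = np.zeros_like(all_csf)
    meshed[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    rest = np.argwhere(all_csf & ~meshed)
    if len(rest):
        tree = cKDTree(domain.mesh.nodes)
        centers = head.index_to_world(rest)
        _, nearest = tree.query(centers)
        u_rest = field.node_values[nearest]
        out[rest[:, 0], rest[:, 1], rest[:, 2]] = np.where(
            u_rest > theta, int(Tissue.CSF1), int(Tissue.CSF2)).astype(out.dtype)

    return VoxelHeadModel(out, head.spacing, head.origin.copy())


def split_csf(head: VoxelHeadModel, theta: float = 0.6, a: float = 1.0,
              with_fissure_plate: bool = True) -> VoxelHeadModel:
    """Convenience wrapper: build the CSF domain, solve the Laplace
    problem and apply the threshold split."""
    domain = build_csf_domain(head, a=a, with_fissure_plate=with_fissure_plate)
    field = solve_csf_laplace(domain)
    return threshold_split(field, domain, head, theta=theta)
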