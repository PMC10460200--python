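"""Tetrahedral meshes for the FEM solvers.

Two mesh sources are provided:

* :func:`voxel_to_tetmesh` — a conforming tetrahedralization of a
  labelled voxel volume.  Every voxel is split into six tetrahedra
  (Kuhn subdivision, all cubes sharing the same main-diagonal
  orientation, hence face-consistent across neighbours).  An optional
  refinement mask splits selected voxels into eight subvoxels; cells
  touching the refined region become star-shaped "transition" cells
  (tetrahedral fans from the cube centre) so the mesh stays conforming
  without hanging nodes.

* :func:`spherical_shell_mesh` / :func:`ball_mesh` — structured meshes
  built from subdivided icosahedra, used for validation against
  closed-form solutions on smooth geometries.

Node coordinates are in mm.  Tet labels inherit the parent voxel's
tissue label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TetMesh", "voxel_to_tetmesh", "spherical_shell_mesh", "ball_mesh",
           "icosphere"]


@dataclass
class TetMesh:
    """Conforming labelled tetrahedral mesh with tagged boundary triangles."""

    nodes: np.ndarray          # (n, 3) mm
    tets: np.ndarray           # (m, 4) node ids
    labels: np.ndarray         # (m,) tissue / region label per tet
    boundary_tris: np.ndarray  # (b, 3) node ids on the domain boundary
    boundary_neighbor: np.ndarray = field(default=None)  # (b,) label across the boundary

    def __post_init__(self) -> None:
        if self.boundary_neighbor is None:
            self.boundary_neighbor = np.zeros(len(self.boundary_tris), dtype=int)

    # -- measures ---------------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        v = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                      np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
        return np.abs(v) / 6.0

    def volume_by_label(self) -> dict[int, float]:
        vols = self.tet_volumes()
        return {int(l): float(vols[self.labels == l].sum())
                for l in np.unique(self.labels)}

    def boundary_areas(self) -> np.ndarray:
        p = self.nodes[self.boundary_tris]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def boundary_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_tris].mean(axis=1)

    def edge_lengths(self, tet_subset: np.ndarray | None = None) -> np.ndarray:
        tets = self.tets if tet_subset is None else self.tets[tet_subset]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.vstack([np.sort(tets[:, p], axis=1) for p in pairs])
        e = np.unique(e, axis=0)
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    # -- I/O (neutral text format) ----------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(path, nodes=self.nodes, tets=self.tets,
                            labels=self.labels, boundary_tris=self.boundary_tris,
                            boundary_neighbor=self.boundary_neighbor)

    @classmethod
    def load(cls, path) -> "TetMesh":
        d = np.load(path)
        return cls(d["nodes"], d["tets"], d["labels"], d["boundary_tris"],
                   d["boundary_neighbor"])


# ---------------------------------------------------------------------------
# voxel grid -> tetrahedra
# ---------------------------------------------------------------------------

# local corner code: c = 4*di + 2*dj + dk.  The six Kuhn tets run along the
# main diagonal 0 -> 7, inserting the axes in each of the 6 orders.
_KUHN_TETS = np.array([
    (0, 4, 6, 7),  # x, y, z
    (0, 4, 5, 7),  # x, z, y
    (0, 2, 6, 7),  # y, x, z
    (0, 2, 3, 7),  # y, z, x
    (0, 1, 5, 7),  # z, x, y
    (0, 1, 3, 7),  # z, y, x
])

# corner offsets in doubled coordinates (0 or 2) for corner code c
_CORNER_OFF = np.array([[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)]) * 2

# for each face (axis, side): the four corner codes, ordered so that the
# Kuhn-consistent diagonal connects entry 0 ("min corner") and entry 2
_FACE_CORNERS = {
    (0, 0): (0, 1, 3, 2), (0, 1): (4, 5, 7, 6),
    (1, 0): (0, 1, 5, 4), (1, 1): (2, 3, 7, 6),
    (2, 0): (0, 2, 6, 4), (2, 1): (1, 3, 7, 5),
}


def _key(d, NyD, NzD):
    """Doubled-coordinate integer triples -> scalar node keys."""
    d = np.asarray(d)
    return (d[..., 0].astype(np.int64) * NyD + d[..., 1]) * NzD + d[..., 2]


def voxel_to_tetmesh(labels: np.ndarray, spacing: float,
                     origin: np.ndarray | None = None,
                     include_mask: np.ndarray | None = None,
                     refine_mask: np.ndarray | None = None) -> TetMesh:
    """Tetrahedralize the voxels of ``labels`` selected by ``include_mask``
    (default: all non-background voxels).

    ``refine_mask`` marks voxels to split into 8 subvoxels; the
    surrounding layer of cells is converted to conforming transition
    fans.  Per-tissue volumes are preserved exactly (the decomposition
    tiles each voxel).  Boundary triangles carry the label of the voxel
    on the far side (0 outside the array).
    """
    labels = np.asarray(labels)
    nx, ny, nz = labels.shape
    if origin is None:
        origin = np.zeros(3)
    include = labels > 0 if include_mask is None else np.asarray(include_mask, bool)
    if not include.any():
        raise ValueError("empty domain")
    if refine_mask is None:
        refined = np.zeros_like(include)
    else:
        refined = np.asarray(refine_mask, bool) & include

    # transition cells: included, not refined, 26-adjacent to a refined cell
    if refined.any():
        from scipy import ndimage
        halo = ndimage.binary_dilation(refined, structure=np.ones((3, 3, 3), bool))
        transition = include & ~refined & halo
    else:
        transition = np.zeros_like(include)
    coarse = include & ~refined & ~transition

    NyD, NzD = 2 * ny + 1, 2 * nz + 1

    def neighbor_label(ijk, axis, side):
        n = list(ijk)
        n[axis] += 1 if side else -1
        if n[axis] < 0 or n[axis] >= labels.shape[axis]:
            return 0
        return int(labels[tuple(n)])

    def neighbor_included(ijk, axis, side):
        n = list(ijk)
        n[axis] += 1 if side else -1
        if n[axis] < 0 or n[axis] >= labels.shape[axis]:
            return False
        return bool(include[tuple(n)])

    def neighbor_refined(ijk, axis, side):
        n = list(ijk)
        n[axis] += 1 if side else -1
        if n[axis] < 0 or n[axis] >= labels.shape[axis]:
            return False
        return bool(refined[tuple(n)])

    tet_keys = []     # arrays (m_i, 4) of node keys
    tet_labels = []
    btri_keys = []    # arrays (b_i, 3)
    btri_neighbor = []

    # ---- coarse Kuhn cells (vectorized) --------------------------------
    cvox = np.argwhere(coarse)
    if len(cvox):
        base = 2 * cvox  # doubled coords of corner (0,0,0)
        corner_keys = _key(base[:, None, :] + _CORNER_OFF[None, :, :], NyD, NzD)  # (n,8)
        tk = corner_keys[:, _KUHN_TETS]            # (n, 6, 4)
        tet_keys.append(tk.reshape(-1, 4))
        tet_labels.append(np.repeat(labels[coarse], 6))
        # boundary faces
        for axis in range(3):
            for side in (0, 1):
                shifted = np.roll(include, -1 if side else 1, axis=axis)
                idx = cvox[:, axis] + (1 if side else -1)
                outside = (idx < 0) | (idx >= labels.shape[axis])
                nb_inc = np.where(outside, False,
                                  shifted[tuple(cvox.T)])
                bmask = ~nb_inc
                if not bmask.any():
                    continue
                cc = _FACE_CORNERS[(axis, side)]
                quad = corner_keys[bmask][:, list(cc)]   # (b, 4)
                tris = np.concatenate([quad[:, [0, 1, 2]], quad[:, [0, 2, 3]]])
                btri_keys.append(tris)
                nb_lab = np.array([neighbor_label(v, axis, side)
                                   for v in cvox[bmask]])
                btri_neighbor.append(np.concatenate([nb_lab, nb_lab]))

    # ---- refined cells: 8 subvoxels x 6 Kuhn tets ----------------------
    rvox = np.argwhere(refined)
    if len(rvox):
        sub_off = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])
        base = 2 * rvox  # (n,3)
        sub_base = base[:, None, :] + sub_off[None, :, :]          # (n,8,3)
        sub_corners = sub_base[:, :, None, :] + (_CORNER_OFF // 2)[None, None, :, :]
        sck = _key(sub_corners, NyD, NzD)                           # (n,8,8)
        tk = sck[:, :, _KUHN_TETS]                                  # (n,8,6,4)
        tet_keys.append(tk.reshape(-1, 4))
        tet_labels.append(np.repeat(labels[refined], 48))
        # boundary subfaces
        for axis in range(3):
            for side in (0, 1):
                bm = np.array([not neighbor_included(v, axis, side) for v in rvox])
                if not bm.any():
                    continue
                cc = _FACE_CORNERS[(axis, side)]
                face_subs = np.where(sub_off[:, axis] == side)[0]  # 4 subvoxels on that face
                quads = sck[bm][:, face_subs][:, :, list(cc)]      # (b,4sub,4)
                quads = quads.reshape(-1, 4)
                tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
                btri_keys.append(tris)
                nb_lab = np.array([neighbor_label(v, axis, side) for v in rvox[bm]])
                nb_lab = np.repeat(nb_lab, 4)
                btri_neighbor.append(np.concatenate([nb_lab, nb_lab]))

    # ---- transition cells: fans from the cube centre -------------------
    # edge midpoint exists iff the edge is shared with >= 1 refined voxel
    def edge_has_midpoint(mid_d):
        """mid_d: doubled coords of an edge midpoint (exactly one odd coord)."""
        odd = [a for a in range(3) if mid_d[a] % 2 == 1]
        ax = odd[0]
        lo = [(mid_d[a] // 2) for a in range(3)]
        cells = []
        for da in (0, -1):
            for db in (0, -1):
                c = list(lo)
                axes = [a for a in range(3) if a != ax]
                c[axes[0]] += da
                c[axes[1]] += db
                cells.append(tuple(c))
        for c in cells:
            if all(0 <= c[a] < labels.shape[a] for a in range(3)) and refined[c]:
                return True
        return False

    tvox = np.argwhere(transition)
    for v in tvox:
        base = 2 * v
        center = tuple(base + 1)
        ck = _key(np.array(center), NyD, NzD)
        lab = int(labels[tuple(v)])
        for axis in range(3):
            for side in (0, 1):
                cc = _FACE_CORNERS[(axis, side)]
                corners_d = [tuple(base + _CORNER_OFF[c]) for c in cc]
                on_boundary = not neighbor_included(v, axis, side)
                if neighbor_refined(v, axis, side):
                    # full 4-subsquare pattern matching the neighbouring
                    # subvoxel faces: each subsquare split along its own
                    # geometric min-max diagonal
                    a1, a2 = [a for a in range(3) if a != axis]
                    fco = base[axis] + (2 if side else 0)

                    def pt(u, w):
                        p = [0, 0, 0]
                        p[axis] = fco
                        p[a1] = base[a1] + u
                        p[a2] = base[a2] + w
                        return tuple(p)

                    tris = []
                    for u0 in (0, 1):
                        for w0 in (0, 1):
                            p00 = pt(u0, w0)
                            p10 = pt(u0 + 1, w0)
                            p11 = pt(u0 + 1, w0 + 1)
                            p01 = pt(u0, w0 + 1)
                            tris.append((p00, p10, p11))
                            tris.append((p00, p11, p01))
                else:
                    mids = []
                    for a in range(4):
                        p, q = corners_d[a], corners_d[(a + 1) % 4]
                        m = tuple((np.array(p) + np.array(q)) // 2)
                        mids.append(m if edge_has_midpoint(m) else None)
                    if all(m is None for m in mids):
                        tris = [(corners_d[0], corners_d[1], corners_d[2]),
                                (corners_d[0], corners_d[2], corners_d[3])]
                    else:
                        fc = np.array(base + 1)
                        fc[axis] = base[axis] + (2 if side else 0)
                        fc = tuple(fc)
                        ring = []
                        for a in range(4):
                            ring.append(corners_d[a])
                            if mids[a] is not None:
                                ring.append(mids[a])
                        tris = [(ring[a], ring[(a + 1) % len(ring)], fc)
                                for a in range(len(ring))]
                tk = _key(np.array(tris), NyD, NzD)  # (t, 3)
                for t in tk:
                    tet_keys.append(np.array([[ck, t[0], t[1], t[2]]]))
                    tet_labels.append(np.array([lab]))
                if on_boundary:
                    btri_keys.append(tk)
                    btri_neighbor.append(np.full(len(tk), neighbor_label(v, axis, side)))

    all_tets = np.concatenate(tet_keys)
    all_labels = np.concatenate(tet_labels)
    all_btris = np.concatenate(btri_keys) if btri_keys else np.zeros((0, 3), np.int64)
    all_bnb = np.concatenate(btri_neighbor) if btri_neighbor else np.zeros(0, int)

    keys = np.concatenate([all_tets.ravel(), all_btris.ravel()])
    uniq, inv = np.unique(keys, return_inverse=True)
    tets = inv[: all_tets.size].reshape(-1, 4)
    btris = inv[all_tets.size:].reshape(-1, 3)

    kz = uniq % NzD
    ky = (uniq // NzD) % NyD
    kx = uniq // (NzD * NyD)
    nodes = np.stack([kx, ky, kz], axis=1) * (0.5 * spacing) + np.asarray(origin)

    mesh = TetMesh(nodes.astype(float), tets.astype(np.int64),
                   all_labels.astype(int), btris.astype(np.int64), all_bnb)
    # drop degenerate fan triangles (can arise from collinear ring points)
    vols = mesh.tet_volumes()
    keep = vols > 1e-12 * spacing ** 3
    mesh.tets = mesh.tets[keep]
    mesh.labels = mesh.labels[keep]
    return mesh


# ---------------------------------------------------------------------------
# structured icosphere meshes
# ---------------------------------------------------------------------------

def icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: vertices and triangular faces after ``subdiv``
    4-fold refinements of the icosahedron."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdiv):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            k = (min(i, j), max(i, j))
            if k not in cache:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                cache[k] = len(vlist)
                vlist.append(m)
            return cache[k]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    return verts, faces


def _split_prism(prism: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism (v0,v1,v2 bottom; v3,v4,v5 top, vi+3 above
    vi) into three tetrahedra with quad diagonals through each quad's
    globally smallest vertex id — face-consistent across shared quads."""
    rots = [
        (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
        (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
    ]
    gmin = int(np.argmin(prism))
    rot = next(r for r in rots if r[0] == gmin)
    V = [prism[i] for i in rot]
    # remaining quad (V1, V2, V5, V4): diagonal through its smallest vertex
    if min(V[1], V[5]) < min(V[2], V[4]):
        tets = [(V[0], V[1], V[2], V[5]), (V[0], V[1], V[5], V[4]),
                (V[0], V[4], V[5], V[3])]
    else:
        tets = [(V[0], V[1], V[2], V[4]), (V[0], V[4], V[2], V[5]),
                (V[0], V[4], V[5], V[3])]
    return tets


def spherical_shell_mesh(r_in: float, r_out: float, n_layers: int = 4,
                         subdiv: int = 4, label: int = 1):
    """Structured tet mesh of a spherical shell.

    Returns ``(mesh, inner_mask, outer_mask)`` where the masks select the
    boundary triangles on the inner / outer sphere.
    """
    verts, faces = icosphere(subdiv)
    V = len(verts)
    radii = np.linspace(r_in, r_out, n_layers + 1)
    nodes = np.concatenate([verts * r for r in radii])
    tets = []
    for l in range(n_layers):
        for f in faces:
            prism = np.array([l * V + f[0], l * V + f[1], l * V + f[2],
                              (l + 1) * V + f[0], (l + 1) * V + f[1], (l + 1) * V + f[2]])
            tets += _split_prism(prism)
    tets = np.array(tets)
    inner = faces.copy()
    outer = faces + n_layers * V
    btris = np.concatenate([inner, outer])
    inner_mask = np.zeros(len(btris), bool)
    inner_mask[: len(inner)] = True
    mesh = TetMesh(nodes, tets, np.full(len(tets), label),
                   btris, np.zeros(len(btris), int))
    return mesh, inner_mask, ~inner_mask


def ball_mesh(radius: float, n_layers: int = 12, subdiv: int = 3,
              label: int = 1) -> TetMesh:
    """Structured tet mesh of a ball: a central vertex fan surrounded by
    layered icosphere shells."""
    verts, faces = icosphere(subdiv)
    V = len(verts)
    radii = np.linspace(radius / n_layers, radius, n_layers)
    nodes = np.concatenate([np.zeros((1, 3))] + [verts * r for r in radii])
    tets = []
    # innermost fan: centre node 0, first shell at offset 1
    for f in faces:
        tets.append((0, 1 + f[0], 1 + f[1], 1 + f[2]))
    for l in range(n_layers - 1):
        o0, o1 = 1 + l * V, 1 + (l + 1) * V
        for f in faces:
            prism = np.array([o0 + f[0], o0 + f[1], o0 + f[2],
                              o1 + f[0], o1 + f[1], o1 + f[2]])
            tets += _split_prism(prism)
    tets = np.array(tets)
    btris = faces + 1 + (n_layers - 1) * V
    return TetMesh(nodes, tets, np.full(len(tets), label),
                   btris, np.zeros(len(btris), int))
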