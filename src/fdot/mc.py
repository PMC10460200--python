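"""Voxel Monte Carlo photon transport in the frequency domain.

The solver follows the microscopic Beer-Lambert (mBLL) strategy: photon
trajectories are sampled from the scattering coefficients only, and the
absorption enters afterwards through the detected-photon weights

    w_p = exp(-sum_j mu_a_j * l_pj),

where l_pj is the exact chord length of photon p in voxel j.  Because
trajectories are absorption-independent, the absorption can be perturbed
after the simulation ("replay") without re-transporting photons — the
basis of the FD Jacobians in :mod:`fdot.mc_jacobian`.

Transport details
-----------------
* photon packets launch uniformly on the source disk (radius R) and are
  collimated toward the probe's centre of curvature; specular reflection
  at launch is not applied (packets start just inside the boundary with
  full weight);
* free paths are sampled from the local mu_s; a dimensionless optical
  depth is consumed across voxel interfaces, which is equivalent to
  scaling the remaining length by the ratio of old to new scattering
  coefficient; zero-mu_s voxels are traversed ballistically;
* deflections are Henyey-Greenstein with the local anisotropy g;
* voxel traversal is exact axis-aligned ray marching, every intersected
  voxel receives its exact chord length;
* at the exterior boundary a binary reflect/exit decision is drawn from
  the unpolarized Fresnel reflectance (face-normal incidence geometry);
  exits within the patch radius of a detector centre are detected;
* each photon's trajectory is reproducible from (seed, launch index)
  via a per-photon counter-based RNG stream, so detected photons can be
  replayed bit-exactly.

The frequency-domain measurement for one source-detector pair is

    X = sum_p w_p cos(2 pi f t_p),   Y = sum_p w_p sin(2 pi f t_p),

divided by the number of launched photons (unit source strength), with
t_p the total time of flight [ns] and f the modulation frequency [GHz].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import OptodeLayout, VoxelHeadModel
from .measurement import DEFAULT_SDS_MAX, FDMeasurement, MeasurementVector
from .optical import C_VACUUM, OpticalTable, Tissue

from numba import njit

__all__ = ["PhotonRecords", "transport", "replay_transport", "detected_weight",
           "fd_measurement", "assemble_measurement_vector", "mu_a_volume"]


# ---------------------------------------------------------------------------
# counter-based per-photon RNG (splitmix64 seeding + xorshift64*)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _photon_state(seed, idx):
    s = _splitmix64(np.uint64(seed) ^ _splitmix64(np.uint64(idx)))
    if s == np.uint64(0):
        s = np.uint64(0x1234567887654321)
    return s


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    out = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, out


@njit(cache=True, inline="always")
def _uniform(state):
    """Uniform in (0, 1]."""
    state, x = _next_u64(state)
    return state, (np.float64(x >> np.uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _fresnel_reflectance(ci, n1, n2):
    if n1 == n2:
        return 0.0
    if ci > 1.0:
        ci = 1.0
    si = np.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport_kernel(labels, h, mu_s_tab, g_tab, n_tab,
                      src_center, src_normal, src_radius, launch_target,
                      det_pos, det_radius, seed, photon_indices,
                      t_max,
                      out_det, out_tof, out_launch, out_indptr,
                      out_vox, out_len, scratch_path, scratch_touch,
                      out_counts):
    """Trace the photons in ``photon_indices``; store detected photons'
    sparse per-voxel paths.  Returns (n_detected, path_cursor,
    n_processed); stops early when the path store is full."""
    nx, ny, nz = labels.shape
    c = 299.792458  # mm / ns

    # orthonormal frame of the source disk
    ax, ay, az = src_normal[0], src_normal[1], src_normal[2]
    if abs(az) < 0.9:
        ux, uy, uz = ay, -ax, 0.0   # normal x zhat
    else:
        ux, uy, uz = 0.0, az, -ay   # normal x xhat
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = ay * uz - az * uy
    vy = az * ux - ax * uz
    vz = ax * uy - ay * ux

    n_det = out_det.shape[0]
    k = 0          # detected count
    cursor = 0     # path store cursor
    cap_path = out_vox.shape[0]
    cap_det = out_det.shape[0]

    for pi in range(photon_indices.shape[0]):
        idx = photon_indices[pi]
        state = _photon_state(seed, idx)

        # launch point uniform on the disk
        state, u1 = _uniform(state)
        state, u2 = _uniform(state)
        rr = src_radius * np.sqrt(u1)
        th = 2.0 * np.pi * u2
        px = src_center[0] + rr * (np.cos(th) * ux + np.sin(th) * vx)
        py = src_center[1] + rr * (np.cos(th) * uy + np.sin(th) * vy)
        pz = src_center[2] + rr * (np.cos(th) * uz + np.sin(th) * vz)
        dx = launch_target[0] - px
        dy = launch_target[1] - py
        dz = launch_target[2] - pz
        dn = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx, dy, dz = dx / dn, dy / dn, dz / dn

        # advance into the labelled region (vacuum before entry)
        i = int(np.floor(px / h))
        j = int(np.floor(py / h))
        kk = int(np.floor(pz / h))
        entered = False
        guard = 0
        while guard < 1000:
            guard += 1
            if 0 <= i < nx and 0 <= j < ny and 0 <= kk < nz and labels[i, j, kk] > 0:
                entered = True
                break
            # step to the next voxel face
            if dx > 0.0:
                tx = ((i + 1) * h - px) / dx
            elif dx < 0.0:
                tx = (i * h - px) / dx
            else:
                tx = 1e30
            if dy > 0.0:
                ty = ((j + 1) * h - py) / dy
            elif dy < 0.0:
                ty = (j * h - py) / dy
            else:
                ty = 1e30
            if dz > 0.0:
                tz = ((kk + 1) * h - pz) / dz
            elif dz < 0.0:
                tz = (kk * h - pz) / dz
            else:
                tz = 1e30
            tmin = min(tx, ty, tz)
            if tmin > 1e29 or tmin < 0.0:
                break
            px += tmin * dx
            py += tmin * dy
            pz += tmin * dz
            if tx <= ty and tx <= tz:
                i += 1 if dx > 0 else -1
            elif ty <= tz:
                j += 1 if dy > 0 else -1
            else:
                kk += 1 if dz > 0 else -1
            if i < -2 * nx or i > 3 * nx or j < -2 * ny or j > 3 * ny or kk < -2 * nz or kk > 3 * nz:
                break
        if not entered:
            out_counts[3] += 1  # missed the head entirely
            continue

        # transport
        t = 0.0
        n_touch = 0
        state, u = _uniform(state)
        tau = -np.log(u)
        alive = True
        detected_id = -1
        exited = False
        while alive:
            lab = labels[i, j, kk]
            mu_s = mu_s_tab[lab]
            g = g_tab[lab]
            n_med = n_tab[lab]
            # distance to next face
            if dx > 0.0:
                tx = ((i + 1) * h - px) / dx
                sx = 1
            elif dx < 0.0:
                tx = (i * h - px) / dx
                sx = -1
            else:
                tx = 1e30
                sx = 0
            if dy > 0.0:
                ty = ((j + 1) * h - py) / dy
                sy = 1
            elif dy < 0.0:
                ty = (j * h - py) / dy
                sy = -1
            else:
                ty = 1e30
                sy = 0
            if dz > 0.0:
                tz = ((kk + 1) * h - pz) / dz
                sz = 1
            elif dz < 0.0:
                tz = (kk * h - pz) / dz
                sz = -1
            else:
                tz = 1e30
                sz = 0
            tface = min(tx, ty, tz)
            if tface < 0.0:
                tface = 0.0

            flat = (i * ny + j) * nz + kk
            if mu_s > 0.0 and tau < mu_s * tface:
                # scattering event inside this voxel
                l = tau / mu_s
                if scratch_path[flat] == 0.0 and l > 0.0:
                    scratch_touch[n_touch] = flat
                    n_touch += 1
                scratch_path[flat] += l
                t += l * n_med / c
                px += l * dx
                py += l * dy
                pz += l * dz
                # Henyey-Greenstein deflection
                state, u1 = _uniform(state)
                if abs(g) < 1e-6:
                    ct = 2.0 * u1 - 1.0
                else:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                st_ = np.sqrt(max(0.0, 1.0 - ct * ct))
                state, u2 = _uniform(state)
                phi = 2.0 * np.pi * u2
                cp = np.cos(phi)
                sp = np.sin(phi)
                if abs(dz) > 0.99999:
                    ndx = st_ * cp
                    ndy = st_ * sp
                    ndz = ct * (1.0 if dz > 0 else -1.0)
                else:
                    den = np.sqrt(1.0 - dz * dz)
                    ndx = st_ * (dx * dz * cp - dy * sp) / den + dx * ct
                    ndy = st_ * (dy * dz * cp + dx * sp) / den + dy * ct
                    ndz = -st_ * cp * den + dz * ct
                nn = np.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
                dx, dy, dz = ndx / nn, ndy / nn, ndz / nn
                state, u = _uniform(state)
                tau = -np.log(u)
            else:
                # traverse to the face
                l = tface
                if l > 0.0:
                    if scratch_path[flat] == 0.0:
                        scratch_touch[n_touch] = flat
                        n_touch += 1
                    scratch_path[flat] += l
                    t += l * n_med / c
                    tau -= mu_s * l
                px += l * dx
                py += l * dy
                pz += l * dz
                # which face
                if tx <= ty and tx <= tz:
                    axis = 0
                    ni, nj, nk = i + sx, j, kk
                elif ty <= tz:
                    axis = 1
                    ni, nj, nk = i, j + sy, kk
                else:
                    axis = 2
                    ni, nj, nk = i, j, kk + sz
                inside = 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                next_lab = labels[ni, nj, nk] if inside else 0
                if next_lab > 0:
                    i, j, kk = ni, nj, nk
                else:
                    # exterior boundary: Fresnel reflect-or-exit
                    if axis == 0:
                        ci = abs(dx)
                    elif axis == 1:
                        ci = abs(dy)
                    else:
                        ci = abs(dz)
                    R = _fresnel_reflectance(ci, n_med, 1.0)
                    state, u = _uniform(state)
                    if u < R:
                        if axis == 0:
                            dx = -dx
                        elif axis == 1:
                            dy = -dy
                        else:
                            dz = -dz
                    else:
                        # exit: detector check
                        exited = True
                        for d in range(det_pos.shape[0]):
                            ddx = px - det_pos[d, 0]
                            ddy = py - det_pos[d, 1]
                            ddz = pz - det_pos[d, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz <= det_radius * det_radius:
                                detected_id = d
                                break
                        alive = False
            if t > t_max:
                alive = False

        if detected_id >= 0:
            if k >= cap_det or cursor + n_touch > cap_path:
                # store full: clean scratch and report progress
                for q in range(n_touch):
                    scratch_path[scratch_touch[q]] = 0.0
                return k, cursor, pi
            out_det[k] = detected_id
            out_tof[k] = t
            out_launch[k] = idx
            for q in range(n_touch):
                fl = scratch_touch[q]
                out_vox[cursor] = fl
                out_len[cursor] = scratch_path[fl]
                cursor += 1
            out_indptr[k + 1] = cursor
            k += 1
            out_counts[0] += 1
        elif exited:
            out_counts[1] += 1
        else:
            out_counts[2] += 1  # terminated at the time cutoff
        # reset scratch
        for q in range(n_touch):
            scratch_path[scratch_touch[q]] = 0.0

    return k, cursor, photon_indices.shape[0]


# ---------------------------------------------------------------------------
# records container
# ---------------------------------------------------------------------------

@dataclass
class PhotonRecords:
    """Detected-photon records of one source's transport run.

    Sparse per-voxel partial path lengths l_pj [mm] in CSR layout over the
    flattened voxel grid, plus time of flight t_p [ns], detector ids and
    replay handles (seed, launch index)."""

    det_id: np.ndarray       # (k,)
    tof: np.ndarray          # (k,) ns
    launch_idx: np.ndarray   # (k,)
    indptr: np.ndarray       # (k+1,)
    voxel_idx: np.ndarray    # (nnz,) flat voxel index
    path_len: np.ndarray     # (nnz,) mm
    n_launched: int
    grid_shape: tuple[int, int, int]
    spacing: float
    seed: int
    source_id: int = 0
    fate_counts: np.ndarray | None = None  # (detected, escaped, timed_out, missed)

    @property
    def n_detected(self) -> int:
        return len(self.det_id)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz

    def path_matrix(self) -> sparse.csr_matrix:
        """(n_detected, n_voxels) sparse matrix of partial paths [mm]."""
        return sparse.csr_matrix(
            (self.path_len, self.voxel_idx, self.indptr),
            shape=(self.n_detected, self.n_voxels))

    def total_paths(self) -> np.ndarray:
        """Per-photon total path length [mm]."""
        return np.add.reduceat(self.path_len, self.indptr[:-1]) if self.n_detected else np.zeros(0)

    def per_tissue_paths(self, labels: np.ndarray) -> dict[int, np.ndarray]:
        """Per-photon per-tissue total paths [mm]; exact sums of the
        per-voxel entries."""
        flat = labels.ravel()[self.voxel_idx]
        out = {}
        for t in np.unique(flat):
            sel = np.where(flat == int(t), self.path_len, 0.0)
            out[int(t)] = np.add.reduceat(sel, self.indptr[:-1])
        return out

    def save(self, path) -> None:
        np.savez_compressed(path, **{f: getattr(self, f) for f in
                            ("det_id", "tof", "launch_idx", "indptr",
                             "voxel_idx", "path_len")},
                            n_launched=self.n_launched,
                            grid_shape=np.array(self.grid_shape),
                            spacing=self.spacing, seed=self.seed,
                            source_id=self.source_id)

    @classmethod
    def load(cls, path) -> "PhotonRecords":
        d = np.load(path)
        return cls(d["det_id"], d["tof"], d["launch_idx"], d["indptr"],
                   d["voxel_idx"], d["path_len"], int(d["n_launched"]),
                   tuple(int(x) for x in d["grid_shape"]), float(d["spacing"]),
                   int(d["seed"]), int(d["source_id"]))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _source_frame(layout: OptodeLayout, source_id: int):
    c = layout.source_positions[source_id]
    normal = layout.launch_target - c
    nrm = np.linalg.norm(normal)
    if nrm == 0:
        raise ValueError("launch target coincides with the source")
    return c, normal / nrm


def transport(head: VoxelHeadModel, optics: OpticalTable, layout: OptodeLayout,
              source_id: int, n_photons: int, seed: int,
              t_max: float = 5.0,
              photon_indices: np.ndarray | None = None) -> PhotonRecords:
    """Run MC transport for one source and return detected-photon records.

    Deterministic for fixed (seed, launch indices); absorption plays no
    role during transport (mBLL).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    labels = np.ascontiguousarray(head.labels.astype(np.int16))
    max_label = int(labels.max())
    _, mu_s_tab, g_tab, n_tab = optics.as_arrays(max_label)

    src_c, src_n = _source_frame(layout, source_id)
    sd = head.signed_surface_distance(layout.source_positions)
    if np.any(np.abs(sd) > 2 * head.spacing):
        raise ValueError("source patch is not on the head surface")

    # kernel works in grid-local coordinates (origin at voxel (0,0,0) corner)
    org = head.origin
    src_c = np.ascontiguousarray(src_c - org)
    tgt = np.ascontiguousarray(layout.launch_target - org)
    det = np.ascontiguousarray(layout.detector_positions - org)

    if photon_indices is None:
        photon_indices = np.arange(n_photons, dtype=np.int64)
    else:
        photon_indices = np.asarray(photon_indices, dtype=np.int64)

    n_vox = labels.size
    scratch_path = np.zeros(n_vox)
    scratch_touch = np.zeros(n_vox, dtype=np.int64)

    cap_det = max(1024, len(photon_indices) // 20)
    cap_path = cap_det * 256
    chunks = []
    fate = np.zeros(4, np.int64)
    remaining = photon_indices
    while len(remaining):
        out_det = np.zeros(cap_det, np.int32)
        out_tof = np.zeros(cap_det)
        out_launch = np.zeros(cap_det, np.int64)
        out_indptr = np.zeros(cap_det + 1, np.int64)
        out_vox = np.zeros(cap_path, np.int64)
        out_len = np.zeros(cap_path)
        k, cursor, done = _transport_kernel(
            labels, float(head.spacing), mu_s_tab, g_tab, n_tab,
            src_c, np.ascontiguousarray(src_n), float(layout.patch_radius),
            tgt, det, float(layout.patch_radius), np.int64(seed),
            remaining, float(t_max),
            out_det, out_tof, out_launch, out_indptr,
            out_vox, out_len, scratch_path, scratch_touch, fate)
        chunks.append((out_det[:k], out_tof[:k], out_launch[:k],
                       out_indptr[:k + 1].copy(), out_vox[:cursor], out_len[:cursor]))
        if done == len(remaining):
            break
        remaining = remaining[done:]
        cap_det *= 2
        cap_path *= 2

    det_id = np.concatenate([c[0] for c in chunks])
    tof = np.concatenate([c[1] for c in chunks])
    launch = np.concatenate([c[2] for c in chunks])
    vox = np.concatenate([c[4] for c in chunks])
    plen = np.concatenate([c[5] for c in chunks])
    counts = np.concatenate([np.diff(c[3]) for c in chunks]) if len(det_id) else np.zeros(0, np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    return PhotonRecords(det_id, tof, launch, indptr, vox, plen,
                         n_launched=len(photon_indices),
                         grid_shape=labels.shape, spacing=head.spacing,
                         seed=seed, source_id=source_id, fate_counts=fate)


def replay_transport(records: PhotonRecords, head: VoxelHeadModel,
                     optics: OpticalTable, layout: OptodeLayout) -> PhotonRecords:
    """Strict replay: re-trace only the detected photons from their
    (seed, launch index) handles.  Bit-identical to the stored records."""
    out = transport(head, optics, layout, records.source_id,
                    n_photons=max(1, records.n_launched), seed=records.seed,
                    photon_indices=records.launch_idx)
    out.n_launched = records.n_launched
    return out


# ---------------------------------------------------------------------------
# weights and FD measurements
# ---------------------------------------------------------------------------

def mu_a_volume(head: VoxelHeadModel, optics: OpticalTable) -> np.ndarray:
    """Flat per-voxel absorption [mm^-1] from the tissue table."""
    mu_a_tab, _, _, _ = optics.as_arrays(int(head.labels.max()))
    return mu_a_tab[head.labels.ravel()]


def detected_weight(records: PhotonRecords, mu_a: np.ndarray) -> np.ndarray:
    """Detected-photon weights w_p = exp(-sum_j mu_a_j l_pj).

    ``mu_a`` is a flat per-voxel array [mm^-1]; recomputable for any
    absorption after transport (mBLL)."""
    mu_a = np.asarray(mu_a, float).ravel()
    if np.any(mu_a < 0):
        raise ValueError("negative absorption coefficient")
    if mu_a.size != records.n_voxels:
        raise ValueError("absorption grid does not match the record grid")
    od = records.path_matrix() @ mu_a
    return np.exp(-od)


def fd_measurement(records: PhotonRecords, mu_a: np.ndarray, f: float,
                   n_d: int, n_launched: int | None = None) -> list[FDMeasurement]:
    """FD measurements at all detectors for one source's records.

    f is the modulation frequency [GHz]; at f = 0 the imaginary part Y
    and the phase vanish identically."""
    if f < 0:
        raise ValueError("modulation frequency must be nonnegative")
    n_l = records.n_launched if n_launched is None else n_launched
    w = detected_weight(records, mu_a)
    ang = 2.0 * np.pi * f * records.tof
    cw = w * np.cos(ang)
    sw = w * np.sin(ang)
    out = []
    for d in range(n_d):
        sel = records.det_id == d
        out.append(FDMeasurement(X=float(cw[sel].sum() / n_l),
                                 Y=float(sw[sel].sum() / n_l),
                                 n_detected=int(sel.sum())))
    return out


def assemble_measurement_vector(head: VoxelHeadModel, optics: OpticalTable,
                                layout: OptodeLayout, n_photons: int,
                                seed: int, f: float = 0.1,
                                sds_max: float = DEFAULT_SDS_MAX,
                                t_max: float = 5.0,
                                return_records: bool = False):
    """Loop over sources, transport and assemble the source-major
    measurement vector with the SDS mask applied."""
    layout.validate()
    mu_a = mu_a_volume(head, optics)
    n_s, n_d = layout.n_s, layout.n_d
    X = np.zeros(n_s * n_d)
    Y = np.zeros(n_s * n_d)
    ndet = np.zeros(n_s * n_d, int)
    all_records = []
    for k in range(n_s):
        rec = transport(head, optics, layout, k, n_photons,
                        seed=seed + 7919 * k, t_max=t_max)
        ms = fd_measurement(rec, mu_a, f, n_d)
        for j, m in enumerate(ms):
            X[k * n_d + j] = m.X
            Y[k * n_d + j] = m.Y
            ndet[k * n_d + j] = m.n_detected
        if return_records:
            all_records.append(rec)
    vec = MeasurementVector(X, Y, layout.sds_matrix().ravel(), n_s, n_d,
                            f=f, n_detected=ndet, sds_max=sds_max)
    return (vec, all_records) if return_records else vec
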