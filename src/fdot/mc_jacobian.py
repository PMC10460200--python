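"""Frequency-domain 'replay' Jacobians for the Monte Carlo solver.

Under the microscopic Beer-Lambert law the detected weights depend on
the per-voxel absorption only through w_p = exp(-sum_j mu_a_j l_pj), so
the derivatives of the FD measurement components are exact sums over the
detected photons:

    dX/dmu_a_j = -sum_p l_pj w_p cos(2 pi f t_p),
    dY/dmu_a_j = -sum_p l_pj w_p sin(2 pi f t_p),

and the log-amplitude and phase rows follow by the chain rule

    dlnA/dmu_a_j = (X dX + Y dY) / A^2,
    dphi/dmu_a_j = (X dY - Y dX) / A^2.

Because no re-transport is needed, difference-quotient Jacobians under
mu_a +/- delta are cheap as well and serve as an independent validation
of the replay formulas.

Jacobian values are normalized per absorption change in 1 mm^3 of
tissue (i.e. divided by the voxel volume), in mm (ln A rows) and
rad*mm (phase rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .mc import PhotonRecords, detected_weight

__all__ = ["JacobianMatrix", "replay_xy_derivatives", "logamp_phase_jacobian",
           "replay_jacobian", "difference_quotient_jacobian",
           "directional_derivative"]


@dataclass
class JacobianMatrix:
    """Measurement Jacobian w.r.t. per-element absorption.

    ``lnA`` and ``phase`` blocks have one row per masked-in measurement
    (ordered as the MeasurementVector) and one column per model element.
    ``row_pairs`` is the (source, detector) manifest of the rows.
    """

    lnA: np.ndarray            # (m, n_e) mm
    phase: np.ndarray          # (m, n_e) rad mm
    row_pairs: np.ndarray      # (m, 2) (source, detector)
    element_volume: float      # mm^3 used for the per-1mm^3 normalization

    @property
    def m(self) -> int:
        return len(self.lnA)

    @property
    def n_e(self) -> int:
        return self.lnA.shape[1]

    def stacked(self) -> np.ndarray:
        """(2m, n_e) with the ln A block on top of the phase block."""
        return np.vstack([self.lnA, self.phase])

    def save(self, path) -> None:
        np.savez_compressed(path, lnA=self.lnA, phase=self.phase,
                            row_pairs=self.row_pairs,
                            element_volume=self.element_volume)

    @classmethod
    def load(cls, path) -> "JacobianMatrix":
        d = np.load(path)
        return cls(d["lnA"], d["phase"], d["row_pairs"], float(d["element_volume"]))


def _xy_terms(records: PhotonRecords, mu_a: np.ndarray, f: float):
    w = detected_weight(records, mu_a)
    ang = 2.0 * np.pi * f * records.tof
    return w, w * np.cos(ang), w * np.sin(ang)


def replay_xy_derivatives(records: PhotonRecords, mu_a: np.ndarray, f: float,
                          detector: int):
    """Per-voxel dX/dmu_a and dY/dmu_a for one detector [mm per mm^-1].

    Exact sums over the detected photons; zero for voxels no detected
    photon traversed.  Also returns (X, Y) per unit source strength.
    """
    _, cw, sw = _xy_terms(records, mu_a, f)
    sel = records.det_id == detector
    L = records.path_matrix()[sel]
    n_l = records.n_launched
    X = cw[sel].sum() / n_l
    Y = sw[sel].sum() / n_l
    dX = -(L.T @ cw[sel]) / n_l
    dY = -(L.T @ sw[sel]) / n_l
    return np.asarray(dX).ravel(), np.asarray(dY).ravel(), X, Y


def logamp_phase_jacobian(X: float, Y: float, dX: np.ndarray, dY: np.ndarray):
    """Chain-rule reduction of (X, Y) derivatives to ln A and phase rows."""
    A2 = X * X + Y * Y
    if A2 <= 0:
        raise ValueError("zero measurement amplitude: no detected signal")
    d_lnA = (X * dX + Y * dY) / A2
    d_phi = (X * dY - Y * dX) / A2
    return d_lnA, d_phi


def replay_jacobian(records_per_source: list[PhotonRecords], mu_a: np.ndarray,
                    f: float, n_d: int, mask: np.ndarray,
                    voxel_volume: float = 1.0) -> JacobianMatrix:
    """Full 'rf replay' Jacobian over all masked-in source-detector pairs.

    Rows follow the source-major pair ordering restricted to ``mask``;
    values are per absorption change in 1 mm^3 (scaled by the voxel
    volume when voxels differ from 1 mm^3).
    """
    rows_lnA, rows_phi, pairs = [], [], []
    for rec in records_per_source:
        k = rec.source_id
        for j in range(n_d):
            if not mask[k * n_d + j]:
                continue
            dX, dY, X, Y = replay_xy_derivatives(rec, mu_a, f, j)
            d_lnA, d_phi = logamp_phase_jacobian(X, Y, dX, dY)
            rows_lnA.append(d_lnA / voxel_volume)
            rows_phi.append(d_phi / voxel_volume)
            pairs.append((k, j))
    return JacobianMatrix(np.array(rows_lnA), np.array(rows_phi),
                          np.array(pairs, dtype=int), voxel_volume)


def difference_quotient_jacobian(records: PhotonRecords, mu_a: np.ndarray,
                                 f: float, detector: int,
                                 elements: np.ndarray,
                                 delta: float = 1e-4,
                                 voxel_volume: float = 1.0):
    """Central difference-quotient estimates of the ln A and phase
    Jacobian entries for the given flat voxel indices.

    Exploits mBLL: perturbing mu_a in voxel j only rescales the weights
    of photons that traversed j — no re-transport.  Same per-1mm^3
    normalization as :func:`replay_jacobian`.
    """
    mu_a = np.asarray(mu_a, float).ravel()
    sel = records.det_id == detector
    L = records.path_matrix()[sel].tocsc()
    n_l = records.n_launched
    w, cw, sw = _xy_terms(records, mu_a, f)
    X0 = cw[sel].sum() / n_l
    Y0 = sw[sel].sum() / n_l
    cw, sw = cw[sel], sw[sel]

    d_lnA = np.zeros(len(elements))
    d_phi = np.zeros(len(elements))
    for i, e in enumerate(np.asarray(elements, int)):
        col = L[:, e]
        rows = col.indices
        l = col.data
        vals = []
        for s in (+1.0, -1.0):
            fac = np.exp(-s * delta * l) - 1.0
            X = X0 + (cw[rows] * fac).sum() / n_l
            Y = Y0 + (sw[rows] * fac).sum() / n_l
            vals.append((np.log(np.hypot(X, Y)), np.arctan2(Y, X)))
        (lnA_p, phi_p), (lnA_m, phi_m) = vals
        d_lnA[i] = (lnA_p - lnA_m) / (2.0 * delta)
        d_phi[i] = (phi_p - phi_m) / (2.0 * delta)
    return d_lnA / voxel_volume, d_phi / voxel_volume


def directional_derivative(records: PhotonRecords, mu_a: np.ndarray, f: float,
                           direction: np.ndarray, n_d: int):
    """Exact directional derivative of (ln A, phase) at every detector
    under an absorption perturbation ``direction`` (flat per-voxel,
    mm^-1): d/d-eps at eps=0 of the measurement with mu_a + eps*direction.

    Used for perturbation studies where only J @ dx is needed.
    """
    w, cw, sw = _xy_terms(records, mu_a, f)
    od = records.path_matrix() @ np.asarray(direction, float).ravel()
    n_l = records.n_launched
    out = []
    for d in range(n_d):
        sel = records.det_id == d
        X = cw[sel].sum() / n_l
        Y = sw[sel].sum() / n_l
        dX = -(od[sel] * cw[sel]).sum() / n_l
        dY = -(od[sel] * sw[sel]).sum() / n_l
        if X == 0 and Y == 0:
            out.append((np.nan, np.nan))
        else:
            out.append(logamp_phase_jacobian(X, Y, dX, dY))
    return out
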