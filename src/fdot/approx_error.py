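"""Approximation-error statistics over a population of anatomies.

The anatomy-induced modelling error in absolute measurements is treated
as additive noise e = y_ref - y_i whose first two moments are estimated
from the registered population,

    mu_e    = 1/N sum_i (y_ref - y_i),
    Gamma_e = 1/(N-1) sum_i (y_ref - y_i - mu_e)(...)^T,

with eigenpairs (lambda_i, v_i) in descending order.  Because Gamma_e is
a sum of N rank-one matrices around the sample mean its rank is at most
N-1; the spectrum is computed through the Gram matrix of the centred
differences (identical nonzero spectrum, numerically clean rank
handling).  The scalar spread measure is STD_e = sqrt(trace(Gamma_e)) =
sqrt(sum lambda_i).

For difference (linearized) measurements the same statistics are formed
for e_dx = (J_ref - J_i) dx, with eigenpairs (eta_i, w_i).

Detectability diagnostics:

* ||P_v mu_e|| / STD_e           — expected anatomy-induced shift vs
                                    spread (P_v projects onto the span of
                                    the positive-eigenvalue eigenvectors);
* ||P_v dy_ref|| / STD_e         — visibility of a perturbation signal
                                    over the anatomical noise;
* |dy_ref . v_i|                 — per-eigendirection projections;
* ||dy_ref|| / ||mu_e_dx||  and  ||P_w dy_ref|| / STD_e_dx for the
  difference-imaging contrast.

Log-amplitude and phase are treated as separate real vectors throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurement import MeasurementVector

__all__ = ["ErrorStatistics", "stats_from_differences", "absolute_error_stats",
           "difference_error_stats", "projection_ratio_mean",
           "signal_visibility", "difference_ratios", "tissue_sweep",
           "cylinder_sensitivity", "eigenvalue_fraction_count"]

_RANK_TOL = 1e-12


@dataclass
class ErrorStatistics:
    """Sample mean, covariance and eigensystem of an error ensemble."""

    mean: np.ndarray          # (m,)
    cov: np.ndarray           # (m, m)
    eigenvalues: np.ndarray   # (min(N, m),) descending, >= 0
    eigenvectors: np.ndarray  # (m, len(eigenvalues)) orthonormal columns
    N: int
    quantity: str = ""

    @property
    def m(self) -> int:
        return len(self.mean)

    @property
    def STD(self) -> float:
        """sqrt(trace(Gamma)) = sqrt(sum of eigenvalues)."""
        return float(np.sqrt(np.trace(self.cov)))

    @property
    def rank(self) -> int:
        lam = self.eigenvalues
        if len(lam) == 0 or lam[0] <= 0:
            return 0
        return int(np.sum(lam > _RANK_TOL * lam[0]))

    def positive_eigenvectors(self) -> np.ndarray:
        return self.eigenvectors[:, : self.rank]

    def project(self, x: np.ndarray) -> np.ndarray:
        """Orthogonal projection onto the span of the positive-eigenvalue
        eigenvectors."""
        V = self.positive_eigenvectors()
        return V @ (V.T @ x)

    def save(self, path) -> None:
        np.savez_compressed(path, mean=self.mean, cov=self.cov,
                            eigenvalues=self.eigenvalues,
                            eigenvectors=self.eigenvectors, N=self.N,
                            quantity=self.quantity)


def stats_from_differences(diffs: np.ndarray, quantity: str = "") -> ErrorStatistics:
    """Moments and eigensystem of an (N, m) array of error realizations.

    Eigen-decomposition through the SVD of the centred rows (Gram
    trick): the nonzero spectrum equals that of the m x m covariance.
    """
    D = np.atleast_2d(np.asarray(diffs, float))
    N, m = D.shape
    if N < 2:
        raise ValueError("need at least two samples")
    mu = D.mean(axis=0)
    C = D - mu
    cov = C.T @ C / (N - 1)
    # SVD of C/sqrt(N-1): right singular vectors are covariance eigenvectors
    _, s, Vt = np.linalg.svd(C / np.sqrt(N - 1.0), full_matrices=False)
    lam = s ** 2
    return ErrorStatistics(mu, cov, lam, Vt.T, N, quantity)


def absolute_error_stats(y_ref: np.ndarray | MeasurementVector,
                         population: list, kind: str = "log_amplitude"
                         ) -> ErrorStatistics:
    """Statistics of the absolute-measurement error y_ref - y_i.

    Accepts raw vectors or MeasurementVector objects (which must share
    mask and ordering; ``kind`` selects log-amplitude or phase)."""
    if isinstance(y_ref, MeasurementVector):
        for y in population:
            if not y_ref.compatible_with(y):
                raise ValueError("measurement orderings/masks do not match")
        ref = y_ref.y(kind)
        diffs = np.array([ref - y.y(kind) for y in population])
    else:
        ref = np.asarray(y_ref, float)
        diffs = np.array([ref - np.asarray(y, float) for y in population])
    return stats_from_differences(diffs, quantity=f"absolute:{kind}")


def difference_error_stats(e_rows: np.ndarray, quantity: str = "difference"
                           ) -> ErrorStatistics:
    """Statistics of precomputed difference-measurement errors
    e_i = (J_ref - J_i) dx, one row per anatomy."""
    return stats_from_differences(e_rows, quantity=quantity)


def projection_ratio_mean(stats: ErrorStatistics) -> float:
    """||P_v mu_e|| / STD_e: expected anatomy-induced shift relative to
    the anatomy-induced spread."""
    std = stats.STD
    if std <= 0:
        raise ValueError("degenerate statistics: STD = 0")
    return float(np.linalg.norm(stats.project(stats.mean)) / std)


def signal_visibility(delta_y_ref: np.ndarray, stats: ErrorStatistics
                      ) -> tuple[float, np.ndarray]:
    """(||P_v dy_ref|| / STD_e, per-eigenvector |dy_ref . v_i|)."""
    dy = np.asarray(delta_y_ref, float)
    std = stats.STD
    ratio = float(np.linalg.norm(stats.project(dy)) / std) if std > 0 else np.inf
    projections = np.abs(stats.eigenvectors.T @ dy)
    return ratio, projections


def difference_ratios(delta_y_ref: np.ndarray, stats: ErrorStatistics
                      ) -> tuple[float, float]:
    """The difference-imaging contrast pair
    (||dy_ref|| / ||mu_e_dx||, ||P_w dy_ref|| / STD_e_dx)."""
    dy = np.asarray(delta_y_ref, float)
    mu_norm = np.linalg.norm(stats.mean)
    r1 = float(np.linalg.norm(dy) / mu_norm) if mu_norm > 0 else np.inf
    r2, _ = signal_visibility(dy, stats)
    return r1, r2


def eigenvalue_fraction_count(stats: ErrorStatistics, fraction: float = 0.95) -> int:
    """Smallest number of leading eigenvalues capturing ``fraction`` of
    the trace (the eigenvalue-decay diagnostic)."""
    lam = stats.eigenvalues
    tot = lam.sum()
    if tot <= 0:
        return 0
    return int(np.searchsorted(np.cumsum(lam) / tot, fraction) + 1)


def tissue_sweep(measure, baseline_y: dict[str, np.ndarray],
                 stats: dict[str, ErrorStatistics],
                 relative_changes: np.ndarray
                 ) -> dict[str, np.ndarray]:
    """Visibility-ratio curves for tissue-wide absorption changes.

    ``measure(relative_change)`` returns {'log_amplitude': vec, 'phase':
    vec} for the reference anatomy with the tissue absorption scaled by
    (1 + relative_change); the caller closes over the solver (MC
    reweighting of stored trajectories, or a DA re-solve).  Returns
    per-kind arrays of ||P_v dy|| / STD over the grid.
    """
    out = {k: np.zeros(len(relative_changes)) for k in baseline_y}
    for i, rc in enumerate(relative_changes):
        if rc == 0.0:
            continue
        y_pert = measure(rc)
        for kind in baseline_y:
            dy = y_pert[kind] - baseline_y[kind]
            out[kind][i], _ = signal_visibility(dy, stats[kind])
    return out


def cylinder_sensitivity(jac_row: np.ndarray, element_centroids: np.ndarray,
                         element_volumes: np.ndarray,
                         surface_point: np.ndarray, inward_normal: np.ndarray,
                         radius: float = 2.5, depth: float = 20.0,
                         slice_thickness: float = 1.0,
                         delta_mu_a: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Depth-sensitivity profile of one measurement row.

    A cylinder of the given radius extends ``depth`` mm into the head
    along the inward normal at ``surface_point`` (the midpoint between
    the source and the detector); for each slice the profile value is
    the measurement derivative under an absorption change of
    ``delta_mu_a`` in that slice, i.e. J~ . dx_j.

    ``jac_row`` is per-1mm^3-normalized (as produced by the Jacobian
    builders), so entries are rescaled by the element volumes.  Summing
    the profile over slices equals applying the row to the whole
    cylinder (partition additivity).
    """
    n = np.asarray(inward_normal, float)
    n = n / np.linalg.norm(n)
    rel = np.asarray(element_centroids, float) - np.asarray(surface_point, float)
    axial = rel @ n
    radial = np.linalg.norm(rel - axial[:, None] * n[:, None].T, axis=1)
    in_cyl = (radial <= radius) & (axial >= 0.0) & (axial <= depth)
    if not in_cyl.any():
        raise ValueError("cylinder does not intersect the model")
    edges = np.arange(0.0, depth + slice_thickness / 2.0, slice_thickness)
    depths = 0.5 * (edges[:-1] + edges[1:])
    raw = jac_row * element_volumes * delta_mu_a
    profile = np.zeros(len(depths))
    for si in range(len(depths)):
        sel = in_cyl & (axial >= edges[si]) & (axial < edges[si + 1])
        profile[si] = raw[sel].sum()
    return depths, profile
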