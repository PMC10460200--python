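"""Voxel head models, cranial point sets and optode layouts.

The head frame convention: the y-axis runs from the inion (Iz) to the
nasion (Nz), the x-axis approximately from the left (LPA) to the right
(RPA) preauricular point, and the z-axis vertically upward.  World
coordinates are in mm; a voxel with index (i, j, k) has its centre at
``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optical import Tissue

__all__ = ["VoxelHeadModel", "CranialPointSet", "OptodeLayout"]

LANDMARK_NAMES = ("Iz", "Nz", "LPA", "RPA", "Cz")


@dataclass
class VoxelHeadModel:
    """Labelled 3D voxel volume of a segmented head.

    Attributes
    ----------
    labels : (nx, ny, nz) integer array
        0 = background, otherwise :class:`~fdot.optical.Tissue` ids.
    spacing : float
        Isotropic voxel edge length [mm].
    origin : (3,) float array
        World coordinate of the voxel-grid corner (0, 0, 0) [mm].
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        self.origin = np.asarray(self.origin, dtype=float)

    # -- coordinates ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing) ** 3

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (may be fractional) -> world mm (voxel centres at +0.5)."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """World mm -> fractional voxel index."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing - 0.5

    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    def centroid(self) -> np.ndarray:
        """World centroid of the head voxels [mm]."""
        idx = np.argwhere(self.head_mask())
        return self.index_to_world(idx.mean(axis=0))

    def tissue_volumes(self) -> dict[Tissue, float]:
        """Per-tissue volume [mm^3]."""
        out = {}
        for t in Tissue:
            if t is Tissue.BACKGROUND:
                continue
            out[t] = float(np.count_nonzero(self.labels == int(t))) * self.voxel_volume
        return out

    # -- surface ----------------------------------------------------------

    def surface_voxel_mask(self) -> np.ndarray:
        """Head voxels with at least one 6-neighbour background voxel."""
        mask = self.head_mask()
        eroded = ndimage.binary_erosion(mask)
        return mask & ~eroded

    def surface_points(self) -> np.ndarray:
        """Point cloud of boundary voxel centres [mm] (a light-weight
        stand-in for a triangulated scalp mesh)."""
        idx = np.argwhere(self.surface_voxel_mask())
        return self.index_to_world(idx)

    def signed_surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance [mm] from points to the head surface
        (positive outside), evaluated on the voxel distance transform."""
        mask = np.pad(self.head_mask(), 1)  # array edges count as background
        d_out = ndimage.distance_transform_edt(~mask, sampling=self.spacing)
        d_in = ndimage.distance_transform_edt(mask, sampling=self.spacing)
        sd = d_out - d_in
        # trilinear interpolation between voxel centres: the interpolated
        # field crosses zero on the staircase surface
        idx = self.world_to_index(np.atleast_2d(points)) + 1.0
        hi = np.array(mask.shape) - 1.0
        clipped = np.clip(idx, 0.0, hi)
        vals = ndimage.map_coordinates(sd, clipped.T, order=1, mode="nearest")
        # points beyond the grid: add the distance to the padded box
        overshoot = np.linalg.norm(idx - clipped, axis=1) * self.spacing
        return vals + overshoot

    def project_to_surface(self, direction: np.ndarray,
                           center: np.ndarray | None = None) -> np.ndarray:
        """March from ``center`` along ``direction`` and return the point on
        the head surface (mm) where the ray leaves the labelled region."""
        if center is None:
            center = self.centroid()
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        step = self.spacing / 4.0
        r_max = np.linalg.norm(np.array(self.shape) * self.spacing)

        def inside(r):
            p = center + r * d
            ijk = np.round(self.world_to_index(p)).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
                return False
            return self.labels[tuple(ijk)] > 0

        last_inside = None
        first_outside = None
        for r in np.arange(0.0, r_max, step):
            if inside(r):
                last_inside = r
            elif last_inside is not None:
                first_outside = r
                break
        if last_inside is None:
            raise ValueError("ray never entered the head")
        if first_outside is None:
            return center + last_inside * d
        # bisect to the voxel-face crossing
        lo, hi = last_inside, first_outside
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if inside(mid):
                lo = mid
            else:
                hi = mid
        return center + 0.5 * (lo + hi) * d

    # -- resampling -------------------------------------------------------

    def downsample_majority(self, factor: int) -> "VoxelHeadModel":
        """Downsample by an integer factor using majority (mode) labels,
        ties broken toward the smaller label id."""
        f = int(factor)
        if f < 1:
            raise ValueError("factor must be >= 1")
        if f == 1:
            return VoxelHeadModel(self.labels.copy(), self.spacing, self.origin.copy())
        nx, ny, nz = (s // f for s in self.shape)
        lab = self.labels[: nx * f, : ny * f, : nz * f]
        blocks = lab.reshape(nx, f, ny, f, nz, f).transpose(0, 2, 4, 1, 3, 5)
        blocks = blocks.reshape(nx, ny, nz, f ** 3)
        n_labels = int(blocks.max()) + 1
        counts = np.zeros((nx, ny, nz, n_labels), dtype=np.int32)
        for l in range(n_labels):
            counts[..., l] = (blocks == l).sum(axis=-1)
        out = counts.argmax(axis=-1).astype(self.labels.dtype)
        return VoxelHeadModel(out, self.spacing * f, self.origin.copy())

    # -- I/O ---------------------------------------------------------------

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.origin + 0.5 * self.spacing
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelHeadModel":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spacing = float(aff[0, 0])
        if not np.allclose(np.diag(aff)[:3], spacing):
            raise ValueError("only isotropic axis-aligned volumes are supported")
        origin = aff[:3, 3] - 0.5 * spacing
        return cls(np.asarray(img.dataobj).astype(np.int16), spacing, origin)

    def to_npz(self, path) -> None:
        np.savez_compressed(path, labels=self.labels, spacing=self.spacing,
                            origin=self.origin)

    @classmethod
    def from_npz(cls, path) -> "VoxelHeadModel":
        d = np.load(path)
        return cls(d["labels"], float(d["spacing"]), d["origin"])


@dataclass
class CranialPointSet:
    """Cranial surface positions: a dense 10-5-style grid plus the five
    anatomical landmarks (Iz, Nz, LPA, RPA, Cz)."""

    surface_points: np.ndarray  # (249, 3) mm
    landmarks: dict[str, np.ndarray]  # name -> (3,) mm

    def __post_init__(self) -> None:
        self.surface_points = np.asarray(self.surface_points, dtype=float)
        if set(self.landmarks) != set(LANDMARK_NAMES):
            raise ValueError(f"landmarks must be exactly {LANDMARK_NAMES}")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    @property
    def n_points(self) -> int:
        return len(self.surface_points) + len(self.landmarks)

    def all_points(self) -> np.ndarray:
        """Stacked (surface points, then Iz, Nz, LPA, RPA, Cz) array."""
        return np.vstack([self.surface_points] +
                         [self.landmarks[k] for k in LANDMARK_NAMES])

    def all_names(self) -> list[str]:
        return [f"P{i:03d}" for i in range(len(self.surface_points))] + list(LANDMARK_NAMES)

    def to_csv(self, path) -> None:
        import pandas as pd

        pts = self.all_points()
        pd.DataFrame({"name": self.all_names(), "x": pts[:, 0],
                      "y": pts[:, 1], "z": pts[:, 2]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CranialPointSet":
        import pandas as pd

        df = pd.read_csv(path)
        lm = {}
        surf = []
        for _, row in df.iterrows():
            p = np.array([row.x, row.y, row.z])
            if row["name"] in LANDMARK_NAMES:
                lm[row["name"]] = p
            else:
                surf.append(p)
        return cls(np.array(surf), lm)


@dataclass
class OptodeLayout:
    """Optode positions on the head boundary.

    Sources and detectors are circular patches of radius ``patch_radius``
    centred on the boundary; all sources launch light toward the common
    ``launch_target`` (the centre of the sphere fitted to the probed
    surface region).
    """

    source_positions: np.ndarray  # (n_s, 3) mm
    detector_positions: np.ndarray  # (n_d, 3) mm
    patch_radius: float = 1.5
    launch_target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_fit_residual: float = float("nan")

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(np.asarray(self.source_positions, float))
        self.detector_positions = np.atleast_2d(np.asarray(self.detector_positions, float))
        self.launch_target = np.asarray(self.launch_target, dtype=float)

    @property
    def n_s(self) -> int:
        return len(self.source_positions)

    @property
    def n_d(self) -> int:
        return len(self.detector_positions)

    def sds_matrix(self) -> np.ndarray:
        """(n_s, n_d) Euclidean source-detector separations [mm]."""
        diff = self.source_positions[:, None, :] - self.detector_positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def min_optode_distance(self) -> float:
        pts = np.vstack([self.source_positions, self.detector_positions])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        return float(d.min())

    def validate(self) -> None:
        if self.min_optode_distance() < 2.0 * self.patch_radius:
            raise ValueError("optode patches overlap")

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, p in enumerate(self.source_positions):
            rows.append(("S%d" % (i + 1), *p))
        for j, p in enumerate(self.detector_positions):
            rows.append(("D%d" % (j + 1), *p))
        rows.append(("target", *self.launch_target))
        pd.DataFrame(rows, columns=["name", "x", "y", "z"]).to_csv(path, index=False)


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Returns (centre [mm], radius [mm], rms residual [mm]).
    """
    p = np.asarray(points, dtype=float)
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    resid = np.linalg.norm(p - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid ** 2)))
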