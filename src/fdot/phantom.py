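"""Synthetic neonatal-head phantom population.

Stands in for a segmented-MRI head database: layered ellipsoidal heads
with a scalp-and-skull shell, a subarachnoid CSF layer, grey matter with
CSF-filled sinusoidal sulci grooves, a white-matter core and ventricles.
Inter-individual variation (overall size, shell/CSF thickness, sulci
count/phase/depth, ventricle size) is drawn per head from configurable
spreads, emulating the spread of head circumferences in a neonatal
cohort at phantom scale.

Pre-split labelling: all CSF outside the ventricles is CSF-1 (the
harmonic split of :mod:`fdot.csf` relabels sulci CSF to CSF-2); the
ventricles are CSF-2 from the start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

from .geometry import VoxelHeadModel, CranialPointSet, OptodeLayout, fit_sphere
from .optical import Tissue

__all__ = [
    "HeadParams",
    "PopulationSpread",
    "generate_head",
    "generate_population",
    "cranial_points",
    "place_probe",
    "probe_template_grid",
    "head_circumference",
]


@dataclass(frozen=True)
class HeadParams:
    """Geometry parameters of one phantom head.

    Lengths in mm.  The outer scalp surface is the ellipsoid with
    semi-axes ``semi_axes`` = (a, b, c) along (x, y, z); the layers are
    nested copies shrunk by the given radial thicknesses measured along
    the ellipsoidal radius.
    """

    semi_axes: tuple[float, float, float] = (32.0, 36.0, 30.0)
    shell_thickness: float = 2.5       # scalp + skull, >= 2 mm
    csf_thickness: float = 2.0         # subarachnoid CSF layer
    gm_thickness: float = 6.0          # grey-matter layer
    n_sulci: int = 8                   # sinusoidal grooves around the vertical axis
    sulci_depth: float = 4.0           # radial groove depth into GM
    sulci_width: float = 0.25          # angular half-width parameter (rad)
    sulci_phase: float = 0.0           # azimuthal phase of the grooves (rad)
    ventricle_radius: float = 5.0      # each of the two lateral ventricles
    spacing: float = 1.0               # voxel edge, 0.5 or 1.0 mm

    def validate(self) -> None:
        a, b, c = self.semi_axes
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.shell_thickness < 2.0:
            raise ValueError("S&S shell must be at least 2 mm thick")
        if self.csf_thickness < 0 or self.gm_thickness <= 0:
            raise ValueError("layer thicknesses must be nonnegative (GM positive)")
        inner = self.shell_thickness + self.csf_thickness + self.gm_thickness
        if inner >= min(a, b, c):
            raise ValueError("layers do not fit inside the head")
        if self.sulci_depth >= self.gm_thickness + self.csf_thickness:
            raise ValueError("sulci grooves must not cut through the grey matter")
        if self.spacing not in (0.5, 1.0):
            raise ValueError("spacing must be 0.5 or 1.0 mm")


@dataclass(frozen=True)
class PopulationSpread:
    """Relative/absolute spreads of the per-head random draws.

    ``size_rel_std`` scales all semi-axes jointly (a relative standard
    deviation, so the head-circumference spread is directly controlled);
    the remaining fields are absolute standard deviations in mm (or
    counts for sulci).  Zero spread yields identical heads.
    """

    size_rel_std: float = 0.035
    shell_std: float = 0.3
    csf_std: float = 0.4
    gm_std: float = 0.8
    sulci_depth_std: float = 0.8
    sulci_count_delta: int = 2
    ventricle_std: float = 0.8

    def is_zero(self) -> bool:
        return all(v == 0 for v in asdict(self).values())


def _ellipsoid_radius(shape: tuple[int, int, int], spacing: float,
                      center: np.ndarray, semi_axes) -> np.ndarray:
    """Normalized ellipsoidal radius rho(x) (outer surface at rho = 1)."""
    a, b, c = semi_axes
    i, j, k = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x = (i + 0.5) * spacing - center[0]
    y = (j + 0.5) * spacing - center[1]
    z = (k + 0.5) * spacing - center[2]
    return np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)


def generate_head(seed: int, params: HeadParams | None = None) -> VoxelHeadModel:
    """Generate one labelled phantom head; deterministic for a fixed seed.

    The seed only matters when ``params.sulci_phase`` is to be randomized
    by the caller (see :func:`generate_population`); head generation
    itself is a deterministic function of ``params``.
    """
    p = params or HeadParams()
    p.validate()
    a, b, c = p.semi_axes
    h = p.spacing
    margin = 2.0 * h
    shape = tuple(int(np.ceil(2 * (s + margin) / h)) for s in (a, b, c))
    center = 0.5 * np.array(shape) * h

    rho = _ellipsoid_radius(shape, h, center, p.semi_axes)
    # layer boundaries as normalized radii (thickness along the minor axis
    # direction scaled by the mean semi-axis for an even layer look)
    r_mean = (a + b + c) / 3.0
    r_shell = 1.0 - p.shell_thickness / r_mean
    r_csf = r_shell - p.csf_thickness / r_mean
    r_gm = r_csf - p.gm_thickness / r_mean

    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= 1.0] = int(Tissue.SCALP_SKULL)
    labels[rho <= r_shell] = int(Tissue.CSF1)
    labels[rho <= r_csf] = int(Tissue.GM)
    labels[rho <= r_gm] = int(Tissue.WM)

    # sinusoidal sulci: radial grooves around the vertical axis carved into
    # the GM crown and filled with CSF
    if p.n_sulci > 0 and p.sulci_depth > 0:
        i, j, k = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        x = (i + 0.5) * h - center[0]
        y = (j + 0.5) * h - center[1]
        z = (k + 0.5) * h - center[2]
        phi = np.arctan2(y / b, x / a)
        crown = z > 0.15 * c  # grooves on the upper head only
        groove = np.cos(p.n_sulci * (phi - p.sulci_phase)) > np.cos(p.sulci_width)
        depth_mask = rho > (r_csf - p.sulci_depth / r_mean)
        carve = groove & crown & depth_mask & (labels == int(Tissue.GM))
        labels[carve] = int(Tissue.CSF1)

    # two lateral ventricles inside WM, labelled CSF-2 from the start
    if p.ventricle_radius > 0:
        for sx in (-1.0, 1.0):
            vc = center + np.array([sx * 0.25 * a, 0.0, -0.1 * c])
            i, j, k = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
            d2 = (((i + 0.5) * h - vc[0]) ** 2 + ((j + 0.5) * h - vc[1]) ** 2
                  + ((k + 0.5) * h - vc[2]) ** 2)
            vent = (d2 <= p.ventricle_radius ** 2) & (labels == int(Tissue.WM))
            labels[vent] = int(Tissue.CSF2)

    return VoxelHeadModel(labels, h, origin=-center)


def _draw_params(rng: np.random.Generator, base: HeadParams,
                 spread: PopulationSpread) -> HeadParams:
    size = 1.0 + spread.size_rel_std * rng.standard_normal()
    size = float(np.clip(size, 0.8, 1.2))
    n_sulci = base.n_sulci
    if spread.sulci_count_delta > 0:
        n_sulci = int(base.n_sulci + rng.integers(-spread.sulci_count_delta,
                                                  spread.sulci_count_delta + 1))
    draw = replace(
        base,
        semi_axes=tuple(s * size for s in base.semi_axes),
        shell_thickness=max(2.0, base.shell_thickness + spread.shell_std * rng.standard_normal()),
        csf_thickness=max(0.5, base.csf_thickness + spread.csf_std * rng.standard_normal()),
        gm_thickness=max(2.0, base.gm_thickness + spread.gm_std * rng.standard_normal()),
        n_sulci=max(0, n_sulci),
        sulci_depth=float(np.clip(base.sulci_depth + spread.sulci_depth_std * rng.standard_normal(),
                                  0.0, base.gm_thickness - 0.5)),
        sulci_phase=float(rng.uniform(0, 2 * np.pi)) if not spread.is_zero() else base.sulci_phase,
        ventricle_radius=max(0.0, base.ventricle_radius + spread.ventricle_std * rng.standard_normal()),
    )
    return draw


def generate_population(N: int, seed: int, base: HeadParams | None = None,
                        spread: PopulationSpread | None = None,
                        with_points: bool = True):
    """Generate N phantom heads with per-head random geometry draws.

    Returns a list of (VoxelHeadModel, CranialPointSet | None) tuples;
    reproducible for a fixed seed, and identical heads for zero spread.
    """
    if N < 2:
        raise ValueError("population size must be at least 2")
    base = base or HeadParams()
    spread = spread or PopulationSpread()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(N):
        p = _draw_params(rng, base, spread)
        head = generate_head(seed + i, p)
        pts = cranial_points(head) if with_points else None
        out.append((head, pts))
    return out


def head_circumference(head: VoxelHeadModel) -> float:
    """Approximate head circumference [mm]: perimeter of the axial head
    outline through the widest section (Ramanujan ellipse formula on the
    half-axis extents)."""
    mask = head.head_mask()
    k = int(np.argmax(mask.sum(axis=(0, 1))))
    sl = mask[:, :, k]
    xs = np.where(sl.any(axis=1))[0]
    ys = np.where(sl.any(axis=0))[0]
    a = 0.5 * (xs[-1] - xs[0] + 1) * head.spacing
    b = 0.5 * (ys[-1] - ys[0] + 1) * head.spacing
    hpar = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1 + 3 * hpar / (10 + np.sqrt(4 - 3 * hpar))))


# ---------------------------------------------------------------------------
# cranial point grid
# ---------------------------------------------------------------------------

# ring layout of the dense cranial grid: colatitude fraction of each ring
# (from the vertex pole down to just below the Nz-Iz-LPA-RPA equator) and
# points per ring; totals 249 positions as in the 10-5 convention
_RING_COUNTS = (6, 12, 18, 24, 24, 24, 24, 24, 24, 24, 24, 21)
_N_RINGS = len(_RING_COUNTS)
assert sum(_RING_COUNTS) == 249


def cranial_points(head: VoxelHeadModel) -> CranialPointSet:
    """Construct the dense cranial grid (249 positions) and the five
    landmarks on the phantom scalp.

    Landmarks are the surface poles along the frame axes (Nz = +y,
    Iz = -y, RPA = +x, LPA = -x, Cz = +z from the head centroid).  The
    grid is built by fractional subdivision: rings of constant colatitude
    between the Cz pole and the landmark equator, azimuthally equally
    subdivided, each direction projected radially onto the scalp surface.
    """
    c = head.centroid()
    lm = {
        "Nz": head.project_to_surface([0, 1, 0], c),
        "Iz": head.project_to_surface([0, -1, 0], c),
        "RPA": head.project_to_surface([1, 0, 0], c),
        "LPA": head.project_to_surface([-1, 0, 0], c),
        "Cz": head.project_to_surface([0, 0, 1], c),
    }
    pts = []
    for r, n_r in enumerate(_RING_COUNTS):
        theta = (r + 1) / _N_RINGS * (0.55 * np.pi)  # slightly past the equator
        for m in range(n_r):
            phi = 2 * np.pi * m / n_r
            d = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi),
                          np.cos(theta)])
            pts.append(head.project_to_surface(d, c))
    return CranialPointSet(np.array(pts), lm)


# ---------------------------------------------------------------------------
# probe placement
# ---------------------------------------------------------------------------

def probe_template_grid(n_side: int = 2, pitch: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Planar optode template: an interleaved (2*n_side^2 optode) grid of
    sources and detectors with the given pitch [mm].

    ``n_side=2`` is the default desk-scale probe (4 sources + 4
    detectors); ``probe_template_grid(4, 10.0)`` approximates a
    high-density 15+15-class probe (here 16+16).
    """
    xs = (np.arange(2 * n_side) - (2 * n_side - 1) / 2.0) * pitch / np.sqrt(2.0)
    src, det = [], []
    for i, x in enumerate(xs):
        for j, y in enumerate(xs):
            (src if (i + j) % 2 == 0 else det).append((x, y))
    return np.array(src), np.array(det)


def _geodesic_separations(points: np.ndarray, center: np.ndarray,
                          radius: float) -> np.ndarray:
    """Pairwise geodesic separations approximated by arcs on the fitted
    sphere (exact on a spherical phantom)."""
    chord = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    arg = np.clip(chord / (2.0 * radius), 0.0, 1.0)
    return 2.0 * radius * np.arcsin(arg)


def place_probe(head: VoxelHeadModel,
                template: tuple[np.ndarray, np.ndarray] | None = None,
                direction=(0.0, 0.0, 1.0),
                patch_radius: float = 1.5,
                n_iter: int = 60) -> OptodeLayout:
    """Press a planar optode template onto the head surface.

    The template is mapped onto the tangent plane at the surface point in
    the given direction and each optode is projected radially toward the
    centre of a sphere fitted to the covered surface region.  A
    coordinate-relaxation pass then nudges the optodes along the surface
    to bring pairwise (geodesic) separations close to the planar template
    separations.  Finally a sphere is fitted to the optode positions and
    its centre stored as the common launch target.
    """
    src2d, det2d = template if template is not None else probe_template_grid()
    n_s = len(src2d)
    plane = np.vstack([src2d, det2d])
    c = head.centroid()
    d0 = np.asarray(direction, float)
    d0 = d0 / np.linalg.norm(d0)
    apex = head.project_to_surface(d0, c)

    # local sphere fitted to the surface region around the apex
    surf = head.surface_points()
    region = surf[np.linalg.norm(surf - apex, axis=1) < 1.5 * (np.abs(plane).max() + 10.0)]
    sc, sr, _ = fit_sphere(region)

    # tangent frame at the apex
    e3 = apex - sc
    e3 /= np.linalg.norm(e3)
    e1 = np.cross([0.0, 1.0, 0.0], e3)
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross([1.0, 0.0, 0.0], e3)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)

    def project_radial(p3):
        """Radial projection toward the fitted-sphere centre onto the scalp."""
        return head.project_to_surface(p3 - sc, sc)

    pts = np.array([project_radial(apex + u * e1 + v * e2) for u, v in plane])

    # template pairwise separations (planar probe geometry)
    d_t = np.linalg.norm(plane[:, None] - plane[None, :], axis=-1)

    def objective(p):
        d_g = _geodesic_separations(p, sc, sr)
        iu = np.triu_indices(len(p), 1)
        return float(np.sum((d_g[iu] - d_t[iu]) ** 2))

    # gradient-free coordinate relaxation on the surface
    step = 0.5 * head.spacing
    best = objective(pts)
    for _ in range(n_iter):
        improved = False
        for i in range(len(pts)):
            n_i = pts[i] - sc
            n_i = n_i / np.linalg.norm(n_i)
            t1 = np.cross(n_i, e2)
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(n_i, t1)
            for dt in (t1, -t1, t2, -t2):
                cand = pts.copy()
                cand[i] = project_radial(pts[i] + step * dt)
                val = objective(cand)
                if val < best - 1e-12:
                    pts, best = cand, val
                    improved = True
        if not improved:
            step *= 0.5
            if step < 0.05 * head.spacing:
                break

    sd = head.signed_surface_distance(pts)
    if np.any(np.abs(sd) > head.spacing):
        raise ValueError("probe projection left the head surface")

    fc, fr, fres = fit_sphere(pts)
    return OptodeLayout(pts[:n_s], pts[n_s:], patch_radius=patch_radius,
                        launch_target=fc, sphere_fit_residual=fres)
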