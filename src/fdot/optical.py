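"""Tissue optical parameters and derived transport coefficients.

The head is segmented into five tissue compartments: combined scalp and
skull (S&S), two cerebrospinal-fluid compartments (semidiffusive
subarachnoid CSF-1 and clearer sulci/ventricle CSF-2), grey matter (GM)
and white matter (WM).  Each compartment carries an absorption
coefficient ``mu_a`` [mm^-1], a scattering coefficient ``mu_s`` [mm^-1],
a scattering anisotropy ``g`` (mean cosine of the single-scattering
deflection) and a refractive index ``n``.

Units are fixed package-wide: lengths in mm, time in ns, coefficients in
mm^-1, modulation frequency in GHz (so that ``2*pi*f*t`` is in radians
with ``t`` in ns).

The default parameter table holds literature values for neonatal tissue
at 800 nm.  The clearer CSF compartment is solver specific: the Monte
Carlo solver models it with lowered absorption and scattering, while the
diffusion-approximation solver (whose validity breaks down in clear
fluids) treats it like the semidiffusive subarachnoid CSF.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = [
    "Tissue",
    "TissueOpticalProperties",
    "OpticalTable",
    "C_VACUUM",
    "reduced_scattering",
    "diffusion_coefficient",
    "effective_reflection",
    "speed_of_light",
    "default_table",
]

#: Speed of light in vacuum [mm / ns].
C_VACUUM = 299.792458


class Tissue(IntEnum):
    """Voxel labels of the five-compartment head segmentation (0 = background)."""

    BACKGROUND = 0
    SCALP_SKULL = 1
    CSF1 = 2
    CSF2 = 3
    GM = 4
    WM = 5


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Optical parameters of one tissue compartment.

    Attributes
    ----------
    tissue : Tissue
        Compartment label.
    mu_a : float
        Absorption coefficient [mm^-1], > 0.
    mu_s : float
        Scattering coefficient [mm^-1], >= 0.
    g : float
        Scattering anisotropy, in [-1, 1].
    n : float
        Refractive index, >= 1.
    """

    tissue: Tissue
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be nonnegative, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient (1 - g) mu_s [mm^-1]."""
        return reduced_scattering(self.mu_s, self.g)

    @property
    def kappa(self) -> float:
        """Diffusion coefficient 1 / (3 (mu_a + mu_s')) [mm]."""
        return diffusion_coefficient(self.mu_a, self.mu_s_reduced)

    @property
    def c_medium(self) -> float:
        """Speed of light in the medium [mm / ns]."""
        return speed_of_light(self.n)


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = (1 - g) mu_s [mm^-1]."""
    if np.any(np.abs(g) > 1.0):
        raise ValueError("anisotropy g must lie in [-1, 1]")
    if np.any(np.asarray(mu_s) < 0):
        raise ValueError("mu_s must be nonnegative")
    return (1.0 - g) * mu_s


def diffusion_coefficient(mu_a: float, mu_s_reduced: float) -> float:
    """Diffusion coefficient kappa = 1 / (3 (mu_a + mu_s')) [mm]."""
    denom = 3.0 * (np.asarray(mu_a) + np.asarray(mu_s_reduced))
    if np.any(denom <= 0):
        raise ValueError("mu_a + mu_s' must be positive")
    return 1.0 / denom


def speed_of_light(n: float) -> float:
    """Speed of light in a medium of refractive index n [mm / ns]."""
    return C_VACUUM / n


def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance for light hitting the boundary from
    inside a medium with relative index ``n_rel = n_in / n_out``."""
    cos_i = min(1.0, max(0.0, cos_i))
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:  # total internal reflection
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=64)
def effective_reflection(n_interior: float, n_exterior: float = 1.0) -> float:
    """Effective reflection coefficient rho for the Robin boundary condition
    of the diffusion approximation.

    Computed with the standard effective-reflectance construction: the
    fluence- and current-weighted angular moments of the unpolarized
    Fresnel reflectance are integrated numerically over the hemisphere of
    incidence angles,

        r_phi = int_0^{pi/2} 2 sin(t) cos(t)   R_F(t) dt,
        r_j   = int_0^{pi/2} 3 sin(t) cos(t)^2 R_F(t) dt,

    and combined into  rho = (r_phi + r_j) / (2 - r_phi + r_j).

    Matched indices give rho = 0; rho grows monotonically with the index
    ratio and stays in [0, 1).
    """
    if n_interior < 1.0 or n_exterior < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if n_interior == n_exterior:
        return 0.0
    n_rel = n_interior / n_exterior

    r_phi, _ = quad(
        lambda t: 2.0 * np.sin(t) * np.cos(t) * _fresnel_unpolarized(np.cos(t), n_rel),
        0.0, np.pi / 2.0, limit=200,
    )
    r_j, _ = quad(
        lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2 * _fresnel_unpolarized(np.cos(t), n_rel),
        0.0, np.pi / 2.0, limit=200,
    )
    rho = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return float(min(max(rho, 0.0), 1.0 - 1e-12))


class OpticalTable:
    """Per-tissue optical parameter table with solver-specific overrides.

    The table maps :class:`Tissue` labels to
    :class:`TissueOpticalProperties`.  ``solver`` selects between the
    Monte Carlo variant (``"mc"``, clearer CSF-2) and the diffusion
    approximation variant (``"da"``, CSF-2 treated as CSF-1).
    """

    def __init__(self, entries: dict[Tissue, TissueOpticalProperties]):
        self._entries = dict(entries)

    def __getitem__(self, tissue: Tissue) -> TissueOpticalProperties:
        return self._entries[Tissue(tissue)]

    def __contains__(self, tissue) -> bool:
        return Tissue(tissue) in self._entries

    @property
    def tissues(self) -> list[Tissue]:
        return sorted(self._entries, key=int)

    def __eq__(self, other) -> bool:
        return isinstance(other, OpticalTable) and self._entries == other._entries

    # -- vectorized lookups used by the solvers --------------------------

    def as_arrays(self, max_label: int | None = None):
        """Dense per-label arrays (mu_a, mu_s, g, n) indexed by tissue id.

        Background (label 0) gets zero coefficients and n = 1.
        """
        if max_label is None:
            max_label = max(int(t) for t in self._entries)
        mu_a = np.zeros(max_label + 1)
        mu_s = np.zeros(max_label + 1)
        g = np.zeros(max_label + 1)
        n = np.ones(max_label + 1)
        for t, p in self._entries.items():
            mu_a[int(t)] = p.mu_a
            mu_s[int(t)] = p.mu_s
            g[int(t)] = p.g
            n[int(t)] = p.n
        return mu_a, mu_s, g, n

    def mu_a_of_labels(self, labels: np.ndarray) -> np.ndarray:
        mu_a, _, _, _ = self.as_arrays(int(np.max(labels)) if labels.size else None)
        return mu_a[labels]

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write the table as CSV with header (tissue, mu_a, mu_s, g, n)."""
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(fh)
            w.writerow(["tissue", "mu_a", "mu_s", "g", "n"])
            for t in self.tissues:
                p = self._entries[t]
                w.writerow([t.name, repr(p.mu_a), repr(p.mu_s), repr(p.g), repr(p.n)])
        finally:
            if own:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "OpticalTable":
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        fh = open(path_or_buf, newline="") if own else path_or_buf
        try:
            entries = {}
            for row in csv.DictReader(fh):
                t = Tissue[row["tissue"]]
                entries[t] = TissueOpticalProperties(
                    t, float(row["mu_a"]), float(row["mu_s"]),
                    float(row["g"]), float(row["n"]),
                )
            return cls(entries)
        finally:
            if own:
                fh.close()

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def default_table(solver: str = "mc") -> OpticalTable:
    """Default neonatal tissue optical parameters at 800 nm.

    ``solver="mc"`` uses the clearer CSF-2 variant (mu_a = 0.002,
    mu_s = 0.4 mm^-1); ``solver="da"`` assigns CSF-2 the CSF-1 values.
    """
    if solver not in ("mc", "da"):
        raise ValueError(f"solver must be 'mc' or 'da', got {solver!r}")
    csf2 = (
        TissueOpticalProperties(Tissue.CSF2, 0.002, 0.4, 0.9, 1.4)
        if solver == "mc"
        else TissueOpticalProperties(Tissue.CSF2, 0.004, 1.6, 0.9, 1.4)
    )
    return OpticalTable({
        Tissue.SCALP_SKULL: TissueOpticalProperties(Tissue.SCALP_SKULL, 0.015, 16.0, 0.9, 1.4),
        Tissue.CSF1: TissueOpticalProperties(Tissue.CSF1, 0.004, 1.6, 0.9, 1.4),
        Tissue.CSF2: csf2,
        Tissue.GM: TissueOpticalProperties(Tissue.GM, 0.048, 5.0, 0.9, 1.4),
        Tissue.WM: TissueOpticalProperties(Tissue.WM, 0.037, 10.0, 0.9, 1.4),
    })
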