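"""Frequency-domain measurement containers shared by both solvers.

A frequency-domain measurement for one source-detector pair is the
complex intensity X + iY (per unit source strength); the observed
quantities are the log-amplitude ln A = ln sqrt(X^2 + Y^2) and the phase
shift phi = atan2(Y, X).  A full measurement set stacks all pairs in
source-major order (index = source * n_d + detector) and carries a mask
restricting the pairs to a maximum source-detector separation (default
SDS < 55 mm) plus validity flags (pairs with no detected photons are
invalid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FDMeasurement", "MeasurementVector", "DEFAULT_SDS_MAX"]

DEFAULT_SDS_MAX = 55.0


@dataclass
class FDMeasurement:
    """FD measurement of a single source-detector pair."""

    X: float
    Y: float
    n_detected: int = 0

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.X, self.Y))

    @property
    def log_amplitude(self) -> float:
        return float(np.log(self.amplitude))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.Y, self.X))

    @property
    def valid(self) -> bool:
        return self.n_detected > 0 and self.amplitude > 0


@dataclass
class MeasurementVector:
    """FD measurements for all source-detector pairs of a layout.

    ``mask`` selects the pairs entering analysis vectors (SDS filter and
    validity); it must be shared between measurements and Jacobians.
    """

    X: np.ndarray          # (n_s * n_d,)
    Y: np.ndarray
    sds: np.ndarray        # (n_s * n_d,) mm
    n_s: int
    n_d: int
    f: float               # modulation frequency [GHz]
    n_detected: np.ndarray | None = None
    sds_max: float = DEFAULT_SDS_MAX
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Y = np.asarray(self.Y, float)
        self.sds = np.asarray(self.sds, float)
        if len(self.X) != self.n_s * self.n_d:
            raise ValueError("entry count must be n_s * n_d (source-major)")
        if self.mask is None:
            valid = np.hypot(self.X, self.Y) > 0
            if self.n_detected is not None:
                valid &= np.asarray(self.n_detected) > 0
            self.mask = (self.sds < self.sds_max) & valid

    @property
    def n_pairs(self) -> int:
        return len(self.X)

    @property
    def m(self) -> int:
        """Number of masked-in measurements."""
        return int(self.mask.sum())

    def log_amplitude(self, masked: bool = True) -> np.ndarray:
        a = np.hypot(self.X, self.Y)
        with np.errstate(divide="ignore"):
            lnA = np.log(a)
        return lnA[self.mask] if masked else lnA

    def phase(self, masked: bool = True) -> np.ndarray:
        phi = np.arctan2(self.Y, self.X)
        return phi[self.mask] if masked else phi

    def y(self, kind: str, masked: bool = True) -> np.ndarray:
        """Real measurement vector: kind in {'log_amplitude', 'phase'}."""
        if kind in ("log_amplitude", "lnA"):
            return self.log_amplitude(masked)
        if kind in ("phase", "phi"):
            return self.phase(masked)
        raise ValueError(f"unknown measurement kind {kind!r}")

    def pair_index(self, source: int, detector: int) -> int:
        return source * self.n_d + detector

    def compatible_with(self, other: "MeasurementVector") -> bool:
        return (self.n_s == other.n_s and self.n_d == other.n_d
                and np.array_equal(self.mask, other.mask))

    def to_dataframe(self):
        import pandas as pd

        k, j = np.divmod(np.arange(self.n_pairs), self.n_d)
        return pd.DataFrame({
            "source": k + 1, "detector": j + 1, "sds": self.sds,
            "X": self.X, "Y": self.Y,
            "lnA": self.log_amplitude(masked=False),
            "phase": self.phase(masked=False),
            "masked_in": self.mask,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
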