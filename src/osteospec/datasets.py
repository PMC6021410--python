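"""Core containers: spectra with metadata, and named optical windows.

A :class:`SpectralDataset` holds a sample x wavelength absorbance matrix on a
strictly increasing nanometre grid, together with per-sample metadata
(donor, anatomical location, Mankin score).  An :class:`OpticalWindow` is a
named inclusive wavelength interval; the three defaults are the tissue
optical windows in which soft-tissue absorption is comparatively low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "OpticalWindow",
    "DEFAULT_WINDOWS",
    "LOCATIONS",
]

#: The four anatomical sampling locations on the human knee.
LOCATIONS = ("FG", "FLC", "TLP", "TMP")


@dataclass(frozen=True)
class OpticalWindow:
    """Inclusive wavelength interval [lo_nm, hi_nm] with a short name."""

    name: str
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(
                f"window {self.name!r}: lo_nm ({self.lo_nm}) must be < hi_nm ({self.hi_nm})"
            )

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points inside the window (inclusive ends)."""
        wl = np.asarray(wavelengths, dtype=float)
        return (wl >= self.lo_nm) & (wl <= self.hi_nm)


#: First, second and third tissue optical windows (nm).
DEFAULT_WINDOWS = (
    OpticalWindow("OW1", 650.0, 950.0),
    OpticalWindow("OW2", 1100.0, 1350.0),
    OpticalWindow("OW3", 1600.0, 1870.0),
)


@dataclass
class SpectralDataset:
    """Sample x wavelength absorbance matrix plus per-sample metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, length ``p``.
    absorbance
        ``(n, p)`` matrix of absorbance values.
    sample_ids
        Length-``n`` sequence of unique sample identifiers.
    metadata
        Optional DataFrame indexed like ``sample_ids`` with columns such as
        ``donor_id``, ``location``, ``mankin``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{self.wavelengths.size} wavelengths"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.absorbance.shape[0])]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length must match number of spectra")
        if np.isnan(self.absorbance).any():
            raise ValueError("absorbance matrix contains NaN after construction")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def grid_step(self) -> float:
        """Mean grid step in nm (grid assumed uniform where it matters)."""
        return float(np.mean(np.diff(self.wavelengths)))

    def copy_with(self, wavelengths=None, absorbance=None) -> "SpectralDataset":
        return SpectralDataset(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            absorbance=self.absorbance if absorbance is None else absorbance,
            sample_ids=list(self.sample_ids),
            metadata=None if self.metadata is None else self.metadata.copy(),
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write as CSV: one row per sample, wavelength values as columns."""
        df = pd.DataFrame(
            self.absorbance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{w:.1f}" for w in self.wavelengths],
        )
        df.to_csv(path, float_format="%.8f")

    @classmethod
    def from_csv(cls, path, metadata: pd.DataFrame | None = None) -> "SpectralDataset":
        df = pd.read_csv(path, index_col="sample_id")
        wl = np.array([float(c) for c in df.columns])
        return cls(
            wavelengths=wl,
            absorbance=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            metadata=metadata,
        )
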