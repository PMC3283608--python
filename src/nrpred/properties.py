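"""Amino-acid physicochemical property scales and their standardization.

Ten classical property scales over the 20 native amino acids drive the
sequence encoding: hydrophobicity, hydrophilicity, side-chain mass, pK1
(alpha-COOH), pK2 (NH3), isoelectric point at 25 degC, average buried
volume, molecular weight, side-chain volume, and mean polarity.  Before any
scale enters the per-sequence property matrix it is zero-centered and scaled
to unit *population* standard deviation over the 20-letter alphabet, so that
scales with very different natural units (pK units, Daltons, cubic
angstroms) contribute comparably to the covariance features.

The population form (divide by 20) is used deliberately: the conversion runs
over the complete, fixed alphabet, not a sample from it.  The conversion is
idempotent — re-standardizing an already standardized scale returns it
unchanged — and invariant under positive affine rescaling of the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .exceptions import ZeroVarianceScale

#: Canonical one-letter codes, alphabetical — the serialization order of
#: every table in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Property identifiers in canonical order.
PROPERTY_IDS: tuple[str, ...] = tuple(f"PC{i}" for i in range(1, 11))

PROPERTY_DESCRIPTIONS: dict[str, str] = {
    "PC1": "hydrophobicity",
    "PC2": "hydrophilicity",
    "PC3": "side-chain mass",
    "PC4": "pK1 (alpha-COOH)",
    "PC5": "pK2 (NH3)",
    "PC6": "PI (25 C)",
    "PC7": "average buried volume",
    "PC8": "molecular weight",
    "PC9": "side-chain volume",
    "PC10": "mean polarity",
}

#: Version stamp of the embedded reference scales.
REFERENCE_TABLE_VERSION = "pc10-v1"

# Rows in AMINO_ACIDS order, columns in PROPERTY_IDS order.
_RAW_VALUES = np.array(
    [
        # PC1     PC2    PC3    PC4    PC5    PC6    PC7     PC8    PC9    PC10
        [0.62, -0.5, 15, 2.35, 9.87, 6.11, 91.50, 89.09, 27.5, -0.06],   # A
        [0.29, -1.00, 47, 1.71, 10.78, 5.02, 117.7, 121.2, 44.6, 1.36],  # C
        [-0.90, 3.00, 59, 1.88, 9.60, 2.98, 124.5, 133.1, 40.0, -0.80],  # D
        [-0.74, 3.00, 73, 2.19, 9.67, 3.08, 155.1, 147.1, 62.0, -0.77],  # E
        [1.19, -2.50, 91, 2.58, 9.24, 5.91, 203.4, 165.2, 115.5, 1.27],  # F
        [0.48, 0.00, 1, 2.34, 9.60, 6.06, 66.40, 75.07, 0.0, -0.41],     # G
        [-0.40, -0.50, 82, 1.78, 8.97, 7.64, 167.3, 155.2, 79.0, 0.49],  # H
        [1.38, -1.80, 57, 2.32, 9.76, 6.04, 168.8, 131.2, 93.5, 1.31],   # I
        [-1.50, 3.00, 73, 2.20, 8.90, 9.47, 171.3, 146.2, 100.0, -1.18], # K
        [1.06, -1.80, 57, 2.36, 9.60, 6.04, 167.9, 131.2, 93.5, 1.21],   # L
        [0.64, -1.30, 75, 2.28, 9.21, 5.74, 170.8, 149.2, 94.1, 1.27],   # M
        [-0.78, 0.20, 58, 2.18, 9.09, 10.76, 135.2, 132.1, 58.7, -0.48], # N
        [0.12, 0.00, 42, 1.99, 10.60, 6.30, 129.3, 115.1, 41.9, 0.00],   # P
        [-0.85, 0.20, 72, 2.17, 9.13, 5.65, 161.1, 146.2, 80.7, -0.73],  # Q
        [-2.53, 3.00, 101, 2.18, 9.09, 10.76, 202.0, 174.2, 105.0, -0.84],  # R
        [-0.18, 0.30, 31, 2.21, 9.15, 5.68, 99.10, 105.1, 29.3, -0.50],  # S
        [-0.05, -0.40, 45, 2.15, 9.12, 5.60, 122.1, 119.1, 51.3, -0.27], # T
        [1.08, -1.50, 43, 2.29, 9.74, 6.02, 141.7, 117.2, 71.5, 1.09],   # V
        [0.81, -3.40, 130, 2.38, 9.39, 5.88, 237.6, 204.2, 145.5, 0.88], # W
        [0.26, -2.30, 107, 2.20, 9.11, 5.63, 203.6, 181.2, 117.3, 0.33], # Y
    ],
    dtype=float,
)


def standardize(raw_scale) -> np.ndarray:
    """Zero-center a 20-value property scale and scale it to unit spread.

    Parameters
    ----------
    raw_scale : array-like of 20 floats
        One value per amino acid, in a fixed (caller-defined) order.

    Returns
    -------
    numpy.ndarray
        Values with mean 0 and population standard deviation 1, in the
        input order.

    Raises
    ------
    ZeroVarianceScale
        If all 20 values are identical (sigma = 0, division undefined).
    """
    x = np.asarray(raw_scale, dtype=float)
    if x.shape != (20,):
        raise ValueError(f"expected 20 values (one per amino acid), got shape {x.shape}")
    sigma = x.std(ddof=0)
    # relative tolerance: twenty identical values can leave an O(eps) sigma
    if sigma <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ZeroVarianceScale("all 20 values are equal; standard deviation is zero")
    return (x - x.mean()) / sigma


@dataclass(frozen=True)
class PropertyTable:
    """Raw and standardized values of property scales over the 20 amino acids.

    Both frames are indexed by one-letter code (rows, alphabetical) with one
    column per property id.  ``standardized`` always satisfies mean 0 /
    population sd 1 per column.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame = field(repr=False)
    version: str = "custom"

    @property
    def property_ids(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)

    @classmethod
    def from_raw(cls, raw: pd.DataFrame, version: str = "custom") -> "PropertyTable":
        """Build a table from raw scales, computing the standardized frame."""
        raw = raw.loc[list(AMINO_ACIDS)].astype(float)
        std = raw.apply(lambda col: pd.Series(standardize(col.to_numpy()), index=raw.index))
        return cls(raw=raw, standardized=std, version=version)

    def standardized_matrix(self, property_ids=None) -> np.ndarray:
        """Standardized values as a (n_properties, 20) array in canonical order."""
        ids = list(property_ids) if property_ids is not None else list(self.property_ids)
        return self.standardized[ids].to_numpy().T

    def to_tsv(self, path_or_buf) -> None:
        """Write the raw table as TSV: header of property ids, one row per code."""
        self.raw.to_csv(path_or_buf, sep="\t", index_label="aa")

    @classmethod
    def from_tsv(cls, path_or_buf: str | Path | IO[str], version: str = "custom") -> "PropertyTable":
        """Read a raw table written by :meth:`to_tsv` (or user-supplied scales)."""
        raw = pd.read_csv(path_or_buf, sep="\t", index_col="aa")
        missing = set(AMINO_ACIDS) - set(raw.index)
        if missing:
            raise ValueError(f"property table missing amino acids: {sorted(missing)}")
        return cls.from_raw(raw, version=version)


@lru_cache(maxsize=1)
def load_reference_table() -> PropertyTable:
    """The embedded ten-scale reference table (immutable, version-stamped)."""
    raw = pd.DataFrame(_RAW_VALUES, index=list(AMINO_ACIDS), columns=list(PROPERTY_IDS))
    return PropertyTable.from_raw(raw, version=REFERENCE_TABLE_VERSION)
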