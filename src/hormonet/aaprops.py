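"""Amino-acid physicochemical property scales and their standardization.

The sequence-order part of the PseAAC encoding compares residues through
numeric property scales.  Thirty scales covering size, hydropathy,
thermodynamic and secondary-structure tendencies ship with the package
(compiled from published literature values); users can substitute any
table with the same layout.

Each scale is standardized over the 20 canonical residues to zero mean
and unit population standard deviation (denominator 20), so that scales
measured in different units contribute comparably to the correlation
function.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import CANONICAL_AA

__all__ = [
    "PropertyTable",
    "load_property_table",
    "default_property_table",
    "standardize",
]


class PropertyTableError(ValueError):
    """Raised for malformed property tables (missing residues, bad cells)."""


class DegenerateScaleError(ValueError):
    """Raised when a property scale is constant across the 20 residues."""


def standardize(raw_row: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-population-SD transform of a 20-residue scale.

    Uses the population standard deviation (denominator 20).  Raises
    :class:`DegenerateScaleError` for a constant scale, whose
    standardization is undefined.
    """
    raw_row = np.asarray(raw_row, dtype=float)
    if raw_row.shape != (20,):
        raise PropertyTableError(f"expected 20 values, got shape {raw_row.shape}")
    mean = raw_row.mean()
    sd = np.sqrt(np.mean((raw_row - mean) ** 2))
    if sd == 0.0:
        raise DegenerateScaleError("constant property scale has zero variance")
    return (raw_row - mean) / sd


@dataclass(frozen=True)
class PropertyTable:
    """Property scales over the 20 canonical residues, raw and standardized.

    ``raw`` and ``standardized`` are (n_properties, 20) arrays whose
    columns follow :data:`~hormonet.seqio.CANONICAL_AA` order.
    """

    names: tuple[str, ...]
    raw: np.ndarray
    standardized: np.ndarray

    @property
    def n_properties(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown property {name!r}") from None

    def subset(self, names: list[str] | tuple[str, ...]) -> "PropertyTable":
        """Table restricted to ``names``, preserving the given order."""
        idx = [self.index_of(n) for n in names]
        return PropertyTable(
            names=tuple(names),
            raw=self.raw[idx],
            standardized=self.standardized[idx],
        )

    def residue_values(self, standardized: bool = True) -> dict[str, np.ndarray]:
        """Map residue letter -> property-value column vector."""
        mat = self.standardized if standardized else self.raw
        return {aa: mat[:, i].copy() for i, aa in enumerate(CANONICAL_AA)}


def _from_dataframe(df: pd.DataFrame, source: str) -> PropertyTable:
    name_col = df.columns[0]
    residue_cols = [c for c in df.columns[1:]]
    missing = [aa for aa in CANONICAL_AA if aa not in residue_cols]
    if missing:
        raise PropertyTableError(
            f"{source}: missing residue column(s) {''.join(missing)}"
        )
    extra = [c for c in residue_cols if c not in CANONICAL_AA]
    if extra:
        raise PropertyTableError(f"{source}: unexpected column(s) {extra}")
    if len(df) < 1:
        raise PropertyTableError(f"{source}: no property rows")
    names = tuple(str(n) for n in df[name_col])
    # canonicalize column order regardless of file order
    raw = np.empty((len(df), 20), dtype=float)
    for j, aa in enumerate(CANONICAL_AA):
        col = pd.to_numeric(df[aa], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise PropertyTableError(
                f"{source}: non-numeric value at property {names[row]!r}, residue {aa}"
            )
        raw[:, j] = col.to_numpy()
    standardized = np.vstack([standardize(raw[i]) for i in range(len(names))])
    return PropertyTable(names=names, raw=raw, standardized=standardized)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a property table from CSV/TSV.

    Layout: first column holds property names, the remaining 20 columns
    are headed by the one-letter residue codes (any order; columns are
    canonicalized to alphabetical ACDEFGHIKLMNPQRSTVWY order on load).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return _from_dataframe(df, str(path))


def default_property_table() -> PropertyTable:
    """The packaged 30-property table."""
    ref = resources.files("hormonet.data").joinpath("aa_properties.csv")
    with resources.as_file(ref) as path:
        return load_property_table(path)
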