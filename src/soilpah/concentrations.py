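"""Sample-by-compound PAH concentration matrices and their CSV I/O.

A :class:`ConcentrationMatrix` holds non-negative concentrations (ng/g) for n
soil samples over the 16 priority PAHs in catalog order, plus optional
below-detection flags. CSV files carry a ``sample_id`` column followed by the
16 compound abbreviations in any order; columns are reordered to the catalog
on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CompoundCatalog, default_catalog

__all__ = ["ConcentrationMatrix", "read_concentration_table", "substitute_below_mdl"]


@dataclass
class ConcentrationMatrix:
    """n x 16 matrix of PAH concentrations (ng/g), columns in catalog order."""

    sample_ids: list[str]
    values: np.ndarray  # shape (n, 16)
    catalog: CompoundCatalog = field(default_factory=default_catalog)
    below_mdl: np.ndarray | None = None  # boolean flags, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.catalog):
            raise ValueError(f"values must be (n, {len(self.catalog)}), got {self.values.shape}")
        if self.values.shape[0] < 1:
            raise ValueError("at least one sample is required")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentrations must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"compound {self.catalog.abbreviations[j]}"
            )
        if self.below_mdl is not None:
            self.below_mdl = np.asarray(self.below_mdl, dtype=bool)
            if self.below_mdl.shape != self.values.shape:
                raise ValueError("below_mdl flags must match the value shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.catalog.abbreviations)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def totals(self) -> np.ndarray:
        """Per-sample total PAH concentration (ng/g)."""
        return self.values.sum(axis=1)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_concentration_table(path: str | Path, catalog: CompoundCatalog | None = None) -> ConcentrationMatrix:
    """Read a concentration CSV, reordering compound columns to catalog order.

    Raises ValueError listing the missing abbreviations if any compound column
    is absent, and on negative or non-numeric cells (naming row and column).
    """
    catalog = catalog or default_catalog()
    df = pd.read_csv(path)
    missing = [a for a in catalog.abbreviations if a not in df.columns]
    if missing:
        raise ValueError(f"concentration table is missing compound columns: {missing}")

    if "sample_id" in df.columns:
        sample_ids = [str(s) for s in df["sample_id"]]
    else:
        sample_ids = [f"S{i + 1}" for i in range(len(df))]

    block = df[catalog.abbreviations]
    values = np.empty((len(df), len(catalog)), dtype=float)
    for j, abbr in enumerate(catalog.abbreviations):
        col = pd.to_numeric(block[abbr], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValueError(f"non-numeric concentration at row {row + 2}, column {abbr}")
        values[:, j] = col.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative concentration at row {i + 2}, column {catalog.abbreviations[j]}"
        )
    return ConcentrationMatrix(sample_ids=sample_ids, values=values, catalog=catalog)


def substitute_below_mdl(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Replace values below the detection limit by MDL/2 and flag them.

    The MDL/2 substitution is the customary receptor-modelling treatment of
    censored concentrations; values at or above the MDL pass through.
    """
    mdls = np.asarray(matrix.catalog.mdls)
    below = matrix.values < mdls[None, :]
    values = np.where(below, mdls[None, :] / 2.0, matrix.values)
    return ConcentrationMatrix(
        sample_ids=list(matrix.sample_ids),
        values=values,
        catalog=matrix.catalog,
        below_mdl=below,
    )
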