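"""Catalog of the 16 US-EPA priority PAH compounds.

The catalog fixes the canonical column order used by every concentration
matrix in this package, and carries per-compound metadata: ring count,
toxic equivalency factor (TEF, potency relative to benzo[a]pyrene), method
detection limit (MDL, ng/g) and the analytical error fraction entering the
measurement-uncertainty model.

TEFs follow the Nisbet & LaGoy scale universally used in soil PAH risk
assessment (BaP = 1, DBahA = 1, most low-molecular-weight species = 0.001).
MDL and error fraction are laboratory-dependent configuration; the defaults
(1.0 ng/g, 0.1) are typical of GC-MS soil analyses and can be overridden
per compound from a CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Compound", "CompoundCatalog", "default_catalog", "read_catalog_csv"]

DEFAULT_MDL = 1.0  # ng/g
DEFAULT_ERROR_FRACTION = 0.1


@dataclass(frozen=True)
class Compound:
    """One priority PAH: identity, ring count, TEF and uncertainty metadata."""

    name: str
    abbreviation: str
    ring_count: int
    tef: float
    mdl: float = DEFAULT_MDL
    error_fraction: float = DEFAULT_ERROR_FRACTION

    def __post_init__(self) -> None:
        if not (2 <= self.ring_count <= 6):
            raise ValueError(f"{self.abbreviation}: ring count must be in 2..6")
        if self.tef <= 0:
            raise ValueError(f"{self.abbreviation}: TEF must be positive")
        if self.mdl <= 0:
            raise ValueError(f"{self.abbreviation}: MDL must be positive")
        if self.error_fraction <= 0:
            raise ValueError(f"{self.abbreviation}: error fraction must be positive")


# (name, abbreviation, rings, TEF) — canonical order, light to heavy.
_COMPOUND_TABLE = [
    ("naphthalene", "Naph", 2, 0.001),
    ("acenaphthylene", "Acy", 3, 0.001),
    ("acenaphthene", "Ace", 3, 0.001),
    ("fluorene", "Flu", 3, 0.001),
    ("phenanthrene", "Phe", 3, 0.001),
    ("anthracene", "Ant", 3, 0.01),
    ("fluoranthene", "Flt", 4, 0.001),
    ("pyrene", "Pyr", 4, 0.001),
    ("benz[a]anthracene", "BaA", 4, 0.1),
    ("chrysene", "Chr", 4, 0.01),
    ("benzo[b]fluoranthene", "BbF", 5, 0.1),
    ("benzo[k]fluoranthene", "BkF", 5, 0.1),
    ("benzo[a]pyrene", "BaP", 5, 1.0),
    ("indeno[1,2,3-cd]pyrene", "IND", 6, 0.1),
    ("dibenz[a,h]anthracene", "DBahA", 5, 1.0),
    ("benzo[g,h,i]perylene", "BghiP", 6, 0.01),
]

LMW_ABBREVIATIONS = ("Naph", "Acy", "Ace", "Flu", "Phe", "Ant")  # 2-3 rings
HMW_ABBREVIATIONS = tuple(a for _, a, r, _t in _COMPOUND_TABLE if r >= 4)


@dataclass(frozen=True)
class CompoundCatalog:
    """Ordered collection of exactly 16 PAH compounds."""

    compounds: tuple[Compound, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.compounds) != 16:
            raise ValueError(f"catalog must hold exactly 16 compounds, got {len(self.compounds)}")
        abbrs = [c.abbreviation for c in self.compounds]
        if len(set(abbrs)) != 16:
            raise ValueError("compound abbreviations must be unique")

    def __iter__(self):
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def abbreviations(self) -> list[str]:
        return [c.abbreviation for c in self.compounds]

    @property
    def tefs(self) -> list[float]:
        return [c.tef for c in self.compounds]

    @property
    def mdls(self) -> list[float]:
        return [c.mdl for c in self.compounds]

    @property
    def error_fractions(self) -> list[float]:
        return [c.error_fraction for c in self.compounds]

    def index(self, abbreviation: str) -> int:
        return self.abbreviations.index(abbreviation)

    def lmw_indices(self) -> list[int]:
        """Indices of the low-molecular-weight (2-3 ring) compounds."""
        return [i for i, c in enumerate(self.compounds) if c.ring_count <= 3]

    def hmw_indices(self) -> list[int]:
        """Indices of the high-molecular-weight (4-6 ring) compounds."""
        return [i for i, c in enumerate(self.compounds) if c.ring_count >= 4]

    def with_overrides(
        self,
        mdl: dict[str, float] | float | None = None,
        error_fraction: dict[str, float] | float | None = None,
    ) -> "CompoundCatalog":
        """Return a copy with per-compound or uniform MDL / error-fraction overrides."""

        def pick(spec, abbr, current):
            if spec is None:
                return current
            if isinstance(spec, dict):
                return spec.get(abbr, current)
            return float(spec)

        new = tuple(
            replace(
                c,
                mdl=pick(mdl, c.abbreviation, c.mdl),
                error_fraction=pick(error_fraction, c.abbreviation, c.error_fraction),
            )
            for c in self.compounds
        )
        return CompoundCatalog(new)


def default_catalog(mdl: float = DEFAULT_MDL, error_fraction: float = DEFAULT_ERROR_FRACTION) -> CompoundCatalog:
    """The canonical 16-compound catalog with uniform MDL / error fraction."""
    return CompoundCatalog(
        tuple(
            Compound(name, abbr, rings, tef, mdl=mdl, error_fraction=error_fraction)
            for name, abbr, rings, tef in _COMPOUND_TABLE
        )
    )


def read_catalog_csv(path: str | Path) -> CompoundCatalog:
    """Load per-compound MDL / error-fraction / TEF overrides.

    The CSV needs an ``abbreviation`` column; ``tef``, ``mdl`` and
    ``error_fraction`` columns are optional and fall back to the defaults.
    """
    overrides: dict[str, dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            abbr = row["abbreviation"].strip()
            overrides[abbr] = {
                k: float(row[k]) for k in ("tef", "mdl", "error_fraction") if row.get(k) not in (None, "")
            }
    base = default_catalog()
    unknown = set(overrides) - set(base.abbreviations)
    if unknown:
        raise ValueError(f"unknown compound abbreviations in catalog file: {sorted(unknown)}")
    new = tuple(replace(c, **overrides.get(c.abbreviation, {})) for c in base.compounds)
    return CompoundCatalog(new)
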