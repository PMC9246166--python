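"""Study-level records: the 41-study soil PAH compilation and its summaries.

Each record is one published survey of surface-soil PAHs in the Beijing-Tianjin
region (2010-2021), carrying the land-use type, total concentration of the 16
priority PAHs (ng/g dry weight), the BaP-equivalent toxicity (ng/g) and a
contamination label. Totals drive a four-level contamination classification:

    < 200 ng/g           not contaminated
    200 - <600 ng/g      weakly contaminated
    600 - 1000 ng/g      contaminated
    > 1000 ng/g          heavily contaminated

The boundary convention (upper class edge at 600 exclusive, 1000 inclusive) is
the unique assignment consistent with all 41 published labels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "ContaminationLevel",
    "StudyRecord",
    "classify_contamination",
    "load_study_table",
    "summarize_group",
    "count_by_level",
    "LAND_USES",
]

LAND_USES = ("urban", "suburban", "rural")


class ContaminationLevel(enum.IntEnum):
    """Ordered soil contamination classes based on total PAH concentration."""

    NOT_CONTAMINATED = 0
    WEAKLY_CONTAMINATED = 1
    CONTAMINATED = 2
    HEAVILY_CONTAMINATED = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "ContaminationLevel":
        return cls[label.strip().upper()]


@dataclass(frozen=True)
class StudyRecord:
    """One published soil-PAH survey (a row of the compiled study table)."""

    land_use: str
    description: str
    total_pahs: float  # ng/g
    bapeq: float  # ng/g BaP-equivalents
    sampling_depth: str
    contamination_label: ContaminationLevel
    reference: str

    def __post_init__(self) -> None:
        if self.land_use not in LAND_USES:
            raise ValueError(f"land_use must be one of {LAND_USES}, got {self.land_use!r}")
        if not (self.total_pahs > 0 and math.isfinite(self.total_pahs)):
            raise ValueError(f"{self.description!r}: total_pahs must be positive and finite")
        if not (self.bapeq >= 0 and math.isfinite(self.bapeq)):
            raise ValueError(f"{self.description!r}: bapeq must be non-negative and finite")


def classify_contamination(total: float) -> ContaminationLevel:
    """Classify a total PAH concentration (ng/g) into a contamination level."""
    if not math.isfinite(total) or total < 0:
        raise ValueError(f"total PAH concentration must be finite and >= 0, got {total}")
    if total < 200:
        return ContaminationLevel.NOT_CONTAMINATED
    if total < 600:
        return ContaminationLevel.WEAKLY_CONTAMINATED
    if total <= 1000:
        return ContaminationLevel.CONTAMINATED
    return ContaminationLevel.HEAVILY_CONTAMINATED


def load_study_table() -> list[StudyRecord]:
    """Load the bundled 41-study compilation (11 urban, 11 suburban, 19 rural).

    Raises ValueError naming the offending row if the fixture is corrupted.
    """
    with resources.files("soilpah.data").joinpath("table1.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)

    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                StudyRecord(
                    land_use=str(row["land_use"]),
                    description=str(row["description"]),
                    total_pahs=float(row["total_pahs"]),
                    bapeq=float(row["bapeq"]),
                    sampling_depth=str(row["sampling_depth"]),
                    contamination_label=ContaminationLevel.from_label(str(row["contamination_label"])),
                    reference=str(row["reference"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"study table fixture corrupted at row {idx + 2}: {exc}") from exc

    if len(records) != 41:
        raise ValueError(f"study table fixture corrupted: expected 41 records, got {len(records)}")
    counts = {lu: sum(r.land_use == lu for r in records) for lu in LAND_USES}
    if (counts["urban"], counts["suburban"], counts["rural"]) != (11, 11, 19):
        raise ValueError(f"study table fixture corrupted: land-use counts {counts}")
    return records


def summarize_group(records: list[StudyRecord], field: str = "bapeq", stat: str = "mean") -> float:
    """Summary statistic over a group of records.

    field: 'total_pahs' or 'bapeq'; stat: 'mean', 'median', 'min' or 'max'.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    if field not in ("total_pahs", "bapeq"):
        raise ValueError(f"field must be 'total_pahs' or 'bapeq', got {field!r}")
    values = pd.Series([getattr(r, field) for r in records], dtype=float)
    try:
        return float(getattr(values, stat)())
    except AttributeError:
        raise ValueError(f"unsupported statistic {stat!r}") from None


def count_by_level(records: list[StudyRecord]) -> dict[ContaminationLevel, int]:
    """Count records per contamination level, re-derived from the totals.

    Classification is recomputed by :func:`classify_contamination` rather than
    read from the stored labels, so label/threshold consistency is checkable.
    """
    counts = {level: 0 for level in ContaminationLevel}
    for r in records:
        counts[classify_contamination(r.total_pahs)] += 1
    return counts
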