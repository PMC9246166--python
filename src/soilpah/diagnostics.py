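"""Isomer diagnostic ratios for PAH source screening.

Three isomer pair ratios, each computed as numerator/(numerator + partner),
carry the conventional source interpretation:

    BaA/(BaA+Chr):  <0.2 petroleum; 0.2-0.35 mixed; >0.35 wood/coal combustion
    Flt/(Flt+Pyr):  <0.4 petroleum; 0.4-0.5 petroleum combustion;
                    >0.5 biomass/coal combustion
    Ant/(Ant+Phe):  <0.1 petrogenic; >=0.1 combustion

Boundary values fall in the middle/mixed class where one exists, otherwise in
the lower class. Ratios are scale-invariant, so they screen sources without
normalizing the sample. A 0/0 ratio is undefined; such samples are excluded
from classification rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concentrations import ConcentrationMatrix

__all__ = ["RATIO_RULES", "RatioRule", "compute_ratio", "classify_ratio", "ratio_crossplot_table"]


@dataclass(frozen=True)
class RatioRule:
    """Breakpoints (strictly increasing, within [0,1]) and the labels between them."""

    ratio_id: str
    numerator: str
    partner: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]  # len(breakpoints) + 1
    # breakpoint i belongs to labels[boundary_side[i]] (index of the interval)
    boundary_side: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one more label than breakpoints")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if self.breakpoints and not (0 < self.breakpoints[0] and self.breakpoints[-1] < 1):
            raise ValueError("breakpoints must lie inside (0, 1)")


RATIO_RULES: dict[str, RatioRule] = {
    "BaA/(BaA+Chr)": RatioRule(
        ratio_id="BaA/(BaA+Chr)",
        numerator="BaA",
        partner="Chr",
        breakpoints=(0.2, 0.35),
        labels=("petroleum", "mixed petroleum/combustion", "wood/coal combustion"),
        boundary_side=(1, 1),  # 0.2 and 0.35 both to the mixed class
    ),
    "Flt/(Flt+Pyr)": RatioRule(
        ratio_id="Flt/(Flt+Pyr)",
        numerator="Flt",
        partner="Pyr",
        breakpoints=(0.4, 0.5),
        labels=("petroleum", "petroleum combustion", "biomass/coal combustion"),
        boundary_side=(1, 1),
    ),
    "Ant/(Ant+Phe)": RatioRule(
        ratio_id="Ant/(Ant+Phe)",
        numerator="Ant",
        partner="Phe",
        breakpoints=(0.1,),
        labels=("petrogenic", "combustion"),
        boundary_side=(1,),  # no middle class: 0.1 counts as combustion (>= 0.1)
    ),
}


def compute_ratio(sample, ratio_id: str, catalog=None) -> float:
    """Diagnostic ratio for one length-16 concentration vector.

    Returns NaN (undefined) when both constituents are zero.
    """
    from .catalog import default_catalog

    rule = RATIO_RULES[ratio_id]
    catalog = catalog or default_catalog()
    sample = np.asarray(sample, dtype=float)
    num = sample[catalog.index(rule.numerator)]
    part = sample[catalog.index(rule.partner)]
    if not (np.isfinite(num) and np.isfinite(part)) or num < 0 or part < 0:
        raise ValueError(f"{ratio_id}: constituent concentrations must be finite and >= 0")
    total = num + part
    if total == 0:
        return float("nan")
    return float(num / total)


def classify_ratio(ratio_id: str, value: float) -> str:
    """Map a ratio value in [0,1] to its source label."""
    rule = RATIO_RULES[ratio_id]
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{ratio_id}: ratio value {value} outside [0, 1]")
    for i, bp in enumerate(rule.breakpoints):
        if value < bp:
            return rule.labels[i]
        if value == bp:
            return rule.labels[rule.boundary_side[i]]
    return rule.labels[-1]


def ratio_crossplot_table(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Per-sample ratio values and labels for the two conventional cross plots.

    One row per sample with all three ratios; samples with any undefined
    (0/0) ratio are excluded from the table.
    """
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        sample = matrix.values[i]
        row: dict[str, object] = {"sample_id": sid}
        defined = True
        for ratio_id in RATIO_RULES:
            value = compute_ratio(sample, ratio_id, matrix.catalog)
            if np.isnan(value):
                defined = False
                break
            row[ratio_id] = value
            row[f"{ratio_id} label"] = classify_ratio(ratio_id, value)
        if defined:
            rows.append(row)
    columns = ["sample_id"]
    for ratio_id in RATIO_RULES:
        columns += [ratio_id, f"{ratio_id} label"]
    return pd.DataFrame(rows, columns=columns)
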