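"""Submergence-response utilities: DEG timing classes and leaf complexity.

Differentially expressed genes (DEGs) from two precomputed contrasts (1 h
and 4 d of submergence) are classified by response timing — early (1 h
only), throughout (both), late (4 d only) — and leaf shape complexity is
quantified by the Dissection Index DI = perimeter / sqrt(area), a unit-free
measure minimized by a circle at 2*sqrt(pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

_REQUIRED = ("gene", "log2fc", "fdr")


def call_degs(
    table: pd.DataFrame, fdr_max: float = 0.01, min_abs_lfc: float = 1.0
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets at strict thresholds.

    up = {FDR < fdr_max and log2FC > min_abs_lfc};
    down = {FDR < fdr_max and log2FC < -min_abs_lfc}.  Inequalities are
    strict, so genes exactly at a threshold are not called.
    """
    if fdr_max <= 0 or min_abs_lfc <= 0:
        raise ValueError("thresholds must be positive")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    if len(table) and ((table["fdr"] < 0) | (table["fdr"] > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    sig = table[table["fdr"] < fdr_max]
    up = set(sig.loc[sig["log2fc"] > min_abs_lfc, "gene"])
    down = set(sig.loc[sig["log2fc"] < -min_abs_lfc, "gene"])
    return up, down


@dataclass
class TimingClasses:
    early: set[str]
    throughout: set[str]
    late: set[str]

    def counts(self) -> dict[str, int]:
        return {
            "early": len(self.early),
            "throughout": len(self.throughout),
            "late": len(self.late),
        }


def classify_timing(deg_1h: set[str], deg_4d: set[str]) -> TimingClasses:
    """Partition DEGs by response timing across the two time points.

    early = 1 h only, throughout = both, late = 4 d only; the classes are
    disjoint and cover the union.
    """
    deg_1h = set(deg_1h)
    deg_4d = set(deg_4d)
    return TimingClasses(
        early=deg_1h - deg_4d,
        throughout=deg_1h & deg_4d,
        late=deg_4d - deg_1h,
    )


#: Isoperimetric lower bound of the Dissection Index (attained by a circle).
DI_MINIMUM = 2.0 * math.sqrt(math.pi)


@dataclass(frozen=True)
class LeafShape:
    """Perimeter and area of a leaf outline, in consistent length units."""

    perimeter: float
    area: float

    def __post_init__(self):
        if self.perimeter <= 0 or self.area <= 0:
            raise ValueError("perimeter and area must be positive")
        if self.perimeter**2 < 4.0 * math.pi * self.area * (1.0 - 1e-9):
            raise ValueError(
                "perimeter^2 < 4*pi*area violates the isoperimetric bound; "
                "check the measurements"
            )


def dissection_index(shape: LeafShape) -> float:
    """DI = perimeter / sqrt(area); dimensionless, >= 2*sqrt(pi)."""
    return shape.perimeter / math.sqrt(shape.area)
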