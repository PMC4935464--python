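"""Chemotaxis-plate scoring, QC, dilution arithmetic, and learning statistics.

The chemotaxis index of a plate is

    CI = (#Odor - #Control) / (#Odor + #Control + #Other)

so +1 is complete attraction and -1 complete avoidance; animals that never
left the origin do not enter the index.  Plates with fewer than 50 animals
outside the origin are excluded so the index reflects the population.
The plate (assay) is the unit of replication throughout; animals are never
pooled across plates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, anova2_interaction
from .types import PlateCount, ValidationError

__all__ = [
    "chemotaxis_index",
    "plate_qc",
    "average_plate_concentration",
    "score_plates",
    "learning_interaction",
    "learning_index",
    "bonferroni_adjust",
]


def chemotaxis_index(plate: PlateCount) -> float:
    """(#Odor - #Control) / (#Odor + #Control + #Other); undefined when no animal left the origin."""
    denom = plate.n_outside
    if denom == 0:
        raise ValidationError(
            f"plate {plate.plate_id!r}: no animals outside the origin, index undefined"
        )
    return (plate.n_odor - plate.n_control) / denom


def plate_qc(plate: PlateCount, min_outside: int = 50) -> tuple[bool, str]:
    """(include, reason): exclude plates with fewer than ``min_outside`` animals outside the origin."""
    if plate.n_outside < min_outside:
        return False, f"only {plate.n_outside} animals outside origin (<{min_outside})"
    return True, ""


def average_plate_concentration(
    spot_volume_l: float,
    spot_concentration_m: float,
    plate_volume_l: float,
    n_spots: int = 2,
) -> float:
    """Average molar odor concentration once the point sources disperse through the plate.

    n_spots * spot_volume * spot_concentration / plate_volume.
    """
    if plate_volume_l <= 0:
        raise ValidationError("plate volume must be positive")
    if spot_volume_l < 0 or spot_concentration_m < 0 or n_spots < 0:
        raise ValidationError("volumes, concentrations and spot count must be non-negative")
    return n_spots * spot_volume_l * spot_concentration_m / plate_volume_l


def score_plates(plates: list[PlateCount], min_outside: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply QC then the index; returns (included AssayTable, excluded table with reasons)."""
    rows, excluded = [], []
    for i, p in enumerate(plates):
        pid = p.plate_id or f"plate{i}"
        ok, reason = plate_qc(p, min_outside)
        if not ok:
            excluded.append({"plate_id": pid, "reason": reason})
            continue
        rows.append(
            {
                "plate_id": pid,
                "chemotaxis_index": chemotaxis_index(p),
                "condition": p.condition,
                "group": p.group,
                "histamine": p.histamine,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["plate_id", "reason"])


def learning_interaction(
    table: pd.DataFrame, factor_a: str = "condition", factor_b: str = "group"
) -> tuple[TestResult, pd.DataFrame]:
    """Two-way ANOVA interaction of conditioning with genotype/treatment.

    ``table`` is an AssayTable (one row per included plate) as produced by
    :func:`score_plates`; the interaction term asks whether the conditioning
    effect on the plate-level chemotaxis index differs between groups.
    """
    for col in ("chemotaxis_index", factor_a, factor_b):
        if col not in table.columns:
            raise ValidationError(f"assay table lacks column {col!r}")
    result, cells = anova2_interaction(
        table["chemotaxis_index"], table[factor_a], table[factor_b]
    )
    return result, cells.rename(columns={"a": factor_a, "b": factor_b})


def learning_index(table: pd.DataFrame, group: str | None = None) -> float:
    """Descriptive learning effect: naive mean CI minus conditioned mean CI."""
    sub = table if group is None else table[table["group"] == group]
    naive = sub.loc[sub["condition"] == "naive", "chemotaxis_index"]
    cond = sub.loc[sub["condition"] == "conditioned", "chemotaxis_index"]
    if naive.empty or cond.empty:
        raise ValidationError("need both naive and conditioned plates")
    return float(naive.mean() - cond.mean())


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni correction: min(1, p*m) per entry; m defaults to len(p_values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValidationError("m must be at least the number of p-values")
    return [min(1.0, float(p) * m) for p in p_values]
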