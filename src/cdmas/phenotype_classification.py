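"""Grain-Cd phenotype classification and per-field panel summaries.

A cultivar is a *low-Cd accumulator* in a field when its replicate-mean
grain Cd is strictly below the food-safety threshold (0.2 mg kg^-1 grain Cd
under GB 2762-2022); otherwise it is a high-Cd accumulator — ties at the
threshold are HIGH. A cultivar low in every tested field is a *stably
low-Cd accumulator*, the phenotype marker-assisted screening is after.
Summaries cover the descriptive statistics screening panels report:
concentration range, fold variation, the fraction of cultivars exceeding
the limit, and the cumulative frequency curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._round import round_half_up
from .tabular_io import GRAIN_CD_LIMIT, GRAIN_CD_STANDARD, HIGH, LOW, CdMeasurement

__all__ = [
    "SafetyThreshold",
    "PhenotypeClass",
    "classify_phenotype",
    "per_field_means",
    "classify_panel",
    "stable_low",
    "stable_low_cultivars",
    "fold_variation",
    "exceedance_fraction",
    "cumulative_frequency",
    "summarize_field",
    "write_classification_table",
    "write_cumulative_frequency",
]


@dataclass(frozen=True)
class SafetyThreshold:
    """Regulatory grain-Cd limit used as the LOW/HIGH cut, mg kg^-1."""

    value: float = GRAIN_CD_LIMIT
    standard_name: str = GRAIN_CD_STANDARD

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class PhenotypeClass:
    """One cultivar's replicate-mean grain Cd and class in one field."""

    cultivar_id: str
    field_id: str
    mean_grain_cd: float
    cd_class: str

    def __post_init__(self) -> None:
        if self.cd_class not in (LOW, HIGH):
            raise ValueError(f"cd_class must be {LOW} or {HIGH}")


def classify_phenotype(mean_grain_cd: float,
                       threshold: SafetyThreshold = SafetyThreshold()) -> str:
    """LOW iff strictly below the threshold; the boundary value is HIGH."""
    if mean_grain_cd < 0:
        raise ValueError(f"negative grain Cd {mean_grain_cd}")
    return LOW if mean_grain_cd < threshold.value else HIGH


def per_field_means(measurements: Iterable[CdMeasurement]) -> dict[tuple[str, str], float]:
    """Replicate-mean grain Cd per (cultivar, field)."""
    records = list(measurements)
    if not records:
        raise ValueError("no measurements")
    frame = pd.DataFrame({
        "cultivar": [m.cultivar_id for m in records],
        "field": [m.field_id for m in records],
        "grain_cd": [m.grain_cd for m in records],
    })
    grouped = frame.groupby(["cultivar", "field"], sort=True)["grain_cd"].mean()
    return {key: float(v) for key, v in grouped.items()}


def classify_panel(measurements: Iterable[CdMeasurement],
                   threshold: SafetyThreshold = SafetyThreshold()) -> list[PhenotypeClass]:
    """Classify every cultivar in every field from replicate means."""
    return [
        PhenotypeClass(cultivar, field, mean, classify_phenotype(mean, threshold))
        for (cultivar, field), mean in sorted(per_field_means(measurements).items())
    ]


def stable_low(per_field_classes: Mapping[str, str]) -> bool:
    """True iff the cultivar is LOW in every field it was grown in."""
    if not per_field_classes:
        raise ValueError("no fields supplied")
    for field_id, cls in per_field_classes.items():
        if cls not in (LOW, HIGH):
            raise ValueError(f"field {field_id}: invalid class {cls!r}")
    return all(cls == LOW for cls in per_field_classes.values())


def stable_low_cultivars(classes: Iterable[PhenotypeClass]) -> list[str]:
    """Cultivars classified LOW in every field present (sorted)."""
    by_cultivar: dict[str, dict[str, str]] = {}
    for rec in classes:
        by_cultivar.setdefault(rec.cultivar_id, {})[rec.field_id] = rec.cd_class
    if not by_cultivar:
        raise ValueError("no phenotype classes supplied")
    return sorted(c for c, fields in by_cultivar.items() if stable_low(fields))


def fold_variation(min_cd: float, max_cd: float) -> int:
    """max/min concentration ratio, rounded to the nearest integer
    (half away from zero)."""
    if min_cd <= 0:
        raise ValueError("fold variation undefined for min_cd <= 0")
    if max_cd < min_cd:
        raise ValueError("max_cd must be >= min_cd")
    return int(round_half_up(max_cd / min_cd, 0))


def exceedance_fraction(per_cultivar_means: Sequence[float],
                        threshold: SafetyThreshold = SafetyThreshold()) -> float:
    """Fraction of cultivars at or above the threshold (complement of LOW)."""
    values = list(per_cultivar_means)
    if not values:
        raise ValueError("empty list of cultivar means")
    exceeding = sum(1 for v in values if classify_phenotype(v, threshold) == HIGH)
    return exceeding / len(values)


def cumulative_frequency(per_cultivar_means: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical cumulative frequency curve over cultivar means.

    Returns (concentration, cumulative proportion) pairs at each distinct
    concentration, non-decreasing in both coordinates and ending at 1.
    """
    values = sorted(per_cultivar_means)
    if not values:
        raise ValueError("empty list of cultivar means")
    n = len(values)
    curve: list[tuple[float, float]] = []
    count = 0
    for i, v in enumerate(values):
        count += 1
        if i + 1 == n or values[i + 1] != v:
            curve.append((float(v), count / n))
    return curve


def summarize_field(per_cultivar_means: Sequence[float],
                    threshold: SafetyThreshold = SafetyThreshold()) -> dict[str, float]:
    """Range, fold variation and exceedance for one field's cultivar means."""
    values = list(per_cultivar_means)
    if not values:
        raise ValueError("empty list of cultivar means")
    lo, hi = min(values), max(values)
    return {
        "min_grain_cd": lo,
        "max_grain_cd": hi,
        "fold_variation": fold_variation(lo, hi),
        "exceedance_pct": round_half_up(100.0 * exceedance_fraction(values, threshold), 0),
    }


def write_classification_table(classes: Iterable[PhenotypeClass],
                               path: str | Path) -> None:
    """Emit cultivar x field classification TSV with a stable_low column."""
    records = list(classes)
    stable = set(stable_low_cultivars(records))
    frame = pd.DataFrame({
        "cultivar": [r.cultivar_id for r in records],
        "field": [r.field_id for r in records],
        "mean_grain_cd": [repr(r.mean_grain_cd) for r in records],
        "cd_class": [r.cd_class for r in records],
        "stable_low": [str(r.cultivar_id in stable).lower() for r in records],
    })
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_cumulative_frequency(per_field_means: Mapping[str, Sequence[float]],
                               path: str | Path) -> None:
    """Emit a cumulative-frequency TSV, one curve per field."""
    rows = []
    for field_id in sorted(per_field_means):
        for conc, prop in cumulative_frequency(per_field_means[field_id]):
            rows.append({"field": field_id, "grain_cd": repr(conc),
                         "cumulative_proportion": repr(prop)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
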