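"""Single- and combined-marker prediction of grain-Cd class, and its scoring.

A diagnostic marker predicts a cultivar LOW when the cultivar carries the
marker's designated low-Cd allele. A *combined* marker panel groups
cultivars by their ordered multi-locus allele vector; each distinct vector
is a genotype class (named Multi-LCL1, Multi-LCL2, ... in ascending order of
the class's mean grain Cd) and the class as a whole is labeled LOW or HIGH.
Two labeling rules are supported:

``STABLE_LOW`` (default)
    a class is LOW iff its members' mean grain Cd stays below the safety
    threshold in every field — the class behaves like a stably low-Cd
    accumulator. This is the rule consistent with published combined-panel
    genotype counts, where the combined panel's LOW count matches the
    stably-low classes rather than any union/intersection of single-marker
    calls.
``ALL_LOW_ALLELES``
    a purely genotypic rule: LOW iff the vector carries the low-Cd allele
    at every panel marker. On a one-marker panel this reduces exactly to
    single-marker prediction.

Agreement with observed phenotype classes is scored per field as class-wise
(high/low) and overall accuracies, plus the across-field mean of overall
accuracy — the confusion-count statistics screening studies tabulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._round import round_half_up
from .phenotype_classification import PhenotypeClass, SafetyThreshold
from .tabular_io import HET, HIGH, LOW, MISSING, GenotypeCall, MarkerDef

__all__ = [
    "STABLE_LOW",
    "ALL_LOW_ALLELES",
    "CombinedGenotype",
    "FieldAccuracy",
    "AccuracySummary",
    "predict_from_marker",
    "predictions_from_calls",
    "build_combined_classes",
    "label_combined_classes",
    "predictions_from_classes",
    "score_accuracy",
    "score_from_counts",
    "reconstruct_correct_count",
    "accuracy_table",
    "write_accuracy_table",
    "write_class_membership",
]

STABLE_LOW = "STABLE_LOW"
ALL_LOW_ALLELES = "ALL_LOW_ALLELES"


@dataclass(frozen=True)
class CombinedGenotype:
    """One cultivar's ordered multi-locus allele vector and class assignment."""

    cultivar_id: str
    allele_vector: tuple[str, ...]
    class_name: str
    class_label: str | None = None  # LOW/HIGH once labeled

    def __post_init__(self) -> None:
        if self.class_label is not None and self.class_label not in (LOW, HIGH):
            raise ValueError(f"class_label must be {LOW}/{HIGH} or None")


@dataclass(frozen=True)
class FieldAccuracy:
    """Confusion counts for one field; accuracies derive from the counts."""

    field_id: str
    n_high: int
    n_low: int
    correct_high: int
    correct_low: int

    def __post_init__(self) -> None:
        if not (0 <= self.correct_high <= self.n_high):
            raise ValueError(f"field {self.field_id}: correct_high out of range")
        if not (0 <= self.correct_low <= self.n_low):
            raise ValueError(f"field {self.field_id}: correct_low out of range")
        if self.n_high + self.n_low == 0:
            raise ValueError(f"field {self.field_id}: empty panel")

    @property
    def high_accuracy(self) -> float | None:
        """% of high-Cd-genotype cultivars observed HIGH; None if no such
        cultivars (undefined, not zero)."""
        return None if self.n_high == 0 else 100.0 * self.correct_high / self.n_high

    @property
    def low_accuracy(self) -> float | None:
        return None if self.n_low == 0 else 100.0 * self.correct_low / self.n_low

    @property
    def overall_accuracy(self) -> float:
        return (100.0 * (self.correct_high + self.correct_low)
                / (self.n_high + self.n_low))


@dataclass(frozen=True)
class AccuracySummary:
    """Per-field confusion counts and accuracies for one marker or panel."""

    marker_or_panel: str
    n_high_genotype: int
    n_low_genotype: int
    per_field: tuple[FieldAccuracy, ...]

    def __post_init__(self) -> None:
        for fa in self.per_field:
            if (fa.n_high, fa.n_low) != (self.n_high_genotype, self.n_low_genotype):
                raise ValueError(
                    f"{self.marker_or_panel}: field {fa.field_id} genotype counts "
                    "disagree with panel counts")

    @property
    def mean_accuracy(self) -> float:
        """Unweighted mean of per-field overall accuracies, computed on
        unrounded fractions."""
        overalls = [fa.overall_accuracy for fa in self.per_field]
        return sum(overalls) / len(overalls)


# --- prediction ------------------------------------------------------------


def predict_from_marker(call: GenotypeCall, marker: MarkerDef,
                        het_policy: str = HIGH) -> str | None:
    """LOW iff the call is the marker's low-Cd allele.

    Heterozygous calls follow ``het_policy``: ``HIGH`` (conservative for
    food safety, the default) or ``MISSING`` (returns None, caller
    excludes). Missing calls must be excluded upstream.
    """
    if call.marker_id != marker.marker_id:
        raise ValueError(f"call is for {call.marker_id}, marker is {marker.marker_id}")
    if call.allele == MISSING:
        raise ValueError(f"{call.cultivar_id}@{marker.marker_id}: missing call "
                         "reached prediction; exclude upstream")
    if call.allele == HET:
        if het_policy == HIGH:
            return HIGH
        if het_policy == MISSING:
            return None
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if call.allele not in marker.alleles:
        raise ValueError(f"{call.cultivar_id}@{marker.marker_id}: "
                         f"allele {call.allele!r} not in marker allele set")
    return LOW if call.allele == marker.low_cd_allele else HIGH


def predictions_from_calls(calls: Iterable[GenotypeCall], marker: MarkerDef,
                           het_policy: str = HIGH) -> dict[str, str]:
    """Per-cultivar LOW/HIGH for one marker; missing/unresolved excluded."""
    out: dict[str, str] = {}
    for call in calls:
        if call.marker_id != marker.marker_id or call.allele == MISSING:
            continue
        pred = predict_from_marker(call, marker, het_policy)
        if pred is not None:
            out[call.cultivar_id] = pred
    return out


# --- combined genotype classes ---------------------------------------------


def build_combined_classes(calls: Iterable[GenotypeCall],
                           panel: Sequence[MarkerDef],
                           cultivar_means: Mapping[str, float] | None = None,
                           prefix: str = "Multi-LCL") -> list[CombinedGenotype]:
    """Partition cultivars by their allele vector over the panel markers.

    Every cultivar must carry a resolved call at every panel marker.
    Distinct vectors become classes named ``{prefix}1``, ``{prefix}2``, ...
    ordered by the class's mean grain Cd ascending when ``cultivar_means``
    (across-field cultivar means) are given, else by vector lexicographic
    order; either way the naming is deterministic.
    """
    if not panel:
        raise ValueError("empty marker panel")
    order = [m.marker_id for m in panel]
    by_cultivar: dict[str, dict[str, str]] = {}
    for call in calls:
        by_cultivar.setdefault(call.cultivar_id, {})[call.marker_id] = call.allele
    if not by_cultivar:
        raise ValueError("no genotype calls supplied")
    vectors: dict[str, tuple[str, ...]] = {}
    for cultivar in sorted(by_cultivar):
        alleles = by_cultivar[cultivar]
        for marker_id in order:
            if marker_id not in alleles or alleles[marker_id] == MISSING:
                raise ValueError(
                    f"cultivar {cultivar!r} lacks a resolved call at marker "
                    f"{marker_id!r}")
        vectors[cultivar] = tuple(alleles[m] for m in order)

    members: dict[tuple[str, ...], list[str]] = {}
    for cultivar, vec in vectors.items():
        members.setdefault(vec, []).append(cultivar)

    def sort_key(vec: tuple[str, ...]):
        if cultivar_means is not None:
            cult = members[vec]
            missing = [c for c in cult if c not in cultivar_means]
            if missing:
                raise ValueError(f"no grain-Cd mean for cultivar(s) {missing}")
            return (sum(cultivar_means[c] for c in cult) / len(cult), vec)
        return vec

    names = {vec: f"{prefix}{i}" for i, vec in
             enumerate(sorted(members, key=sort_key), start=1)}
    return [CombinedGenotype(cultivar, vec, names[vec])
            for cultivar, vec in sorted(vectors.items())]


def label_combined_classes(classes: Sequence[CombinedGenotype],
                           phenotypes: Iterable[PhenotypeClass] = (),
                           mode: str = STABLE_LOW,
                           panel: Sequence[MarkerDef] | None = None,
                           threshold: SafetyThreshold = SafetyThreshold(),
                           ) -> list[CombinedGenotype]:
    """Assign each genotype class a LOW/HIGH label.

    ``STABLE_LOW``: LOW iff the class's member-mean grain Cd is below the
    threshold in every field (requires ``phenotypes`` covering every member
    in every field). ``ALL_LOW_ALLELES``: LOW iff the vector is the low-Cd
    allele at every panel marker (requires ``panel``).
    """
    if mode not in (STABLE_LOW, ALL_LOW_ALLELES):
        raise ValueError(f"unknown labeling mode {mode!r}")
    by_class: dict[str, list[CombinedGenotype]] = {}
    for rec in classes:
        by_class.setdefault(rec.class_name, []).append(rec)

    labels: dict[str, str] = {}
    if mode == ALL_LOW_ALLELES:
        if panel is None:
            raise ValueError("ALL_LOW_ALLELES labeling needs the marker panel")
        low_vec = tuple(m.low_cd_allele for m in panel)
        for name, recs in by_class.items():
            labels[name] = LOW if recs[0].allele_vector == low_vec else HIGH
    else:
        means: dict[str, dict[str, float]] = {}
        for ph in phenotypes:
            means.setdefault(ph.cultivar_id, {})[ph.field_id] = ph.mean_grain_cd
        field_ids = sorted({f for per in means.values() for f in per})
        for name, recs in by_class.items():
            cultivars = [r.cultivar_id for r in recs]
            unphenotyped = [c for c in cultivars
                            if c not in means
                            or any(f not in means[c] for f in field_ids)]
            if not field_ids or unphenotyped:
                raise ValueError(
                    f"class {name}: member(s) {unphenotyped or cultivars} lack "
                    "phenotypes in every field")
            stably_low = all(
                sum(means[c][f] for c in cultivars) / len(cultivars) < threshold.value
                for f in field_ids)
            labels[name] = LOW if stably_low else HIGH
    return [replace(rec, class_label=labels[rec.class_name]) for rec in classes]


def predictions_from_classes(labeled: Iterable[CombinedGenotype]) -> dict[str, str]:
    """Per-cultivar LOW/HIGH from labeled combined classes."""
    out: dict[str, str] = {}
    for rec in labeled:
        if rec.class_label is None:
            raise ValueError(f"class {rec.class_name} is unlabeled")
        out[rec.cultivar_id] = rec.class_label
    return out


# --- scoring ---------------------------------------------------------------


def score_accuracy(predicted: Mapping[str, str],
                   observed: Iterable[PhenotypeClass],
                   name: str = "panel") -> AccuracySummary:
    """Score genotype predictions against per-field phenotype classes.

    ``predicted`` maps every cultivar to LOW/HIGH (its genotype class);
    ``observed`` must cover exactly the same cultivars in every field.
    """
    if not predicted:
        raise ValueError("no predictions supplied")
    obs_by_field: dict[str, dict[str, str]] = {}
    for ph in observed:
        obs_by_field.setdefault(ph.field_id, {})[ph.cultivar_id] = ph.cd_class
    if not obs_by_field:
        raise ValueError("no observed phenotype classes supplied")
    cultivars = set(predicted)
    n_high = sum(1 for c in cultivars if predicted[c] == HIGH)
    n_low = len(cultivars) - n_high
    per_field: list[FieldAccuracy] = []
    for field_id in sorted(obs_by_field):
        obs = obs_by_field[field_id]
        if set(obs) != cultivars:
            raise ValueError(
                f"field {field_id}: observed cultivars do not match predictions "
                f"(symmetric difference {sorted(set(obs) ^ cultivars)})")
        correct_high = sum(1 for c in cultivars
                           if predicted[c] == HIGH and obs[c] == HIGH)
        correct_low = sum(1 for c in cultivars
                          if predicted[c] == LOW and obs[c] == LOW)
        per_field.append(FieldAccuracy(field_id, n_high, n_low,
                                       correct_high, correct_low))
    return AccuracySummary(name, n_high, n_low, tuple(per_field))


def reconstruct_correct_count(accuracy_pct: float, n: int) -> int:
    """Integer correct-call count implied by a printed class accuracy:
    ``round(accuracy * n)``, half away from zero."""
    if not 0 <= accuracy_pct <= 100:
        raise ValueError("accuracy percentage outside [0, 100]")
    if n < 0:
        raise ValueError("class size must be >= 0")
    return int(round_half_up(accuracy_pct / 100.0 * n, 0))


def score_from_counts(name: str, n_high: int, n_low: int,
                      field_counts: Mapping[str, tuple[int, int]]) -> AccuracySummary:
    """Build an :class:`AccuracySummary` directly from confusion counts
    (``field -> (correct_high, correct_low)``) — e.g. counts reconstructed
    from a published accuracy table."""
    per_field = tuple(
        FieldAccuracy(field_id, n_high, n_low, ch, cl)
        for field_id, (ch, cl) in sorted(field_counts.items()))
    return AccuracySummary(name, n_high, n_low, per_field)


# --- tabular output --------------------------------------------------------


def _fmt(pct: float | None) -> str:
    return "-" if pct is None else f"{round_half_up(pct, 1):.1f}"


def accuracy_table(summaries: Sequence[AccuracySummary]) -> pd.DataFrame:
    """Accuracy summaries as a display table (percentages half-up, 1 dp;
    undefined class accuracies shown as '-')."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "marker": s.marker_or_panel,
            "n_high_genotype": s.n_high_genotype,
            "n_low_genotype": s.n_low_genotype,
        }
        for fa in s.per_field:
            row[f"{fa.field_id}_high_accuracy"] = _fmt(fa.high_accuracy)
            row[f"{fa.field_id}_low_accuracy"] = _fmt(fa.low_accuracy)
            row[f"{fa.field_id}_overall_accuracy"] = _fmt(fa.overall_accuracy)
        row["mean_accuracy"] = _fmt(s.mean_accuracy)
        rows.append(row)
    return pd.DataFrame(rows)


def write_accuracy_table(summaries: Sequence[AccuracySummary],
                         path: str | Path) -> None:
    accuracy_table(summaries).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_class_membership(classes: Iterable[CombinedGenotype],
                           path: str | Path) -> None:
    rows = [{
        "cultivar": rec.cultivar_id,
        "allele_vector": ",".join(rec.allele_vector),
        "class_name": rec.class_name,
        "class_label": rec.class_label or MISSING,
    } for rec in classes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
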