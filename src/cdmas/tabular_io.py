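"""Typed tabular and sequence I/O for the Cd marker-screening pipeline.

Every table the pipeline touches is tab-separated UTF-8 with a single header
row; ``.`` encodes a missing genotype call. Parsers validate each row against
the record invariants and report failures with 1-based line numbers, so
downstream modules only ever see well-formed typed records. Sequence
coordinates are 0-based half-open throughout; conversion to 1-based happens
only in error messages.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "IUPAC_DNA",
    "IUPAC_SETS",
    "HET",
    "MISSING",
    "LOW",
    "HIGH",
    "GRAIN_CD_LIMIT",
    "GRAIN_CD_STANDARD",
    "SOIL_CD_LIMIT_PH_BELOW_5_5",
    "SOIL_CD_LIMIT_PH_5_5_TO_6_5",
    "SOIL_CD_STANDARD",
    "TableError",
    "MarkerDef",
    "FieldSite",
    "CdMeasurement",
    "GenotypeCall",
    "read_marker_table",
    "write_marker_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_field_table",
    "write_field_table",
    "read_fasta",
    "write_fasta",
]

# --- constants -------------------------------------------------------------

#: Standard IUPAC nucleotide alphabet (uppercase, no gaps, no 'X').
IUPAC_DNA: frozenset[str] = frozenset("ACGTRYSWKMBDHVN")

#: Expansion of each IUPAC symbol to the set of concrete bases it matches.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    c: frozenset(ambiguous_dna_values[c]) for c in sorted(IUPAC_DNA)
}

HET = "HET"
MISSING = "."

LOW = "LOW"
HIGH = "HIGH"

#: Maximum permissible Cd in rice grain, mg kg^-1 (GB 2762-2022).
GRAIN_CD_LIMIT = 0.2
GRAIN_CD_STANDARD = "GB 2762-2022"

#: Soil Cd screening limits for acidic paddy soils, mg kg^-1 (GB 15618-2018).
SOIL_CD_LIMIT_PH_BELOW_5_5 = 0.3
SOIL_CD_LIMIT_PH_5_5_TO_6_5 = 0.4
SOIL_CD_STANDARD = "GB 15618-2018"


class TableError(ValueError):
    """Validation failure in a tabular or FASTA input.

    Carries the offending file, 1-based line number and column name so the
    bad row can be located directly.
    """

    def __init__(self, message: str, *, path: str | Path | None = None,
                 line: int | None = None, column: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column '{column}'")
        prefix = " ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = None if path is None else str(path)
        self.line = line
        self.column = column


# --- domain records --------------------------------------------------------


def _check_iupac(seq: str, *, what: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in IUPAC_DNA:
            raise ValueError(f"{what}: non-IUPAC character {base!r} at position {i}")
    return seq


@dataclass(frozen=True)
class MarkerDef:
    """One CAPS/dCAPS marker assay.

    The amplicon sequence, when present, is the *cut* allele's amplicon: it
    carries the enzyme recognition site spanning ``diagnostic_position`` (the
    polymorphic base, 0-based). The alternative allele destroys that site.
    Markers distributed only as fragment-size assays may carry just
    ``amplicon_length``.
    """

    marker_id: str
    alleles: tuple[str, str]
    enzyme_name: str
    recognition_pattern: str
    cut_allele: str
    low_cd_allele: str
    diagnostic_position: int | None = None
    amplicon: str | None = None
    amplicon_length: int | None = None

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if len(self.alleles) != 2 or len(set(self.alleles)) != 2:
            raise ValueError(f"marker {self.marker_id}: exactly two distinct alleles required")
        for name, allele in (("cut_allele", self.cut_allele),
                             ("low_cd_allele", self.low_cd_allele)):
            if allele not in self.alleles:
                raise ValueError(
                    f"marker {self.marker_id}: {name} {allele!r} not in declared alleles {self.alleles}")
        pattern = _check_iupac(self.recognition_pattern,
                               what=f"marker {self.marker_id} recognition_pattern")
        if not pattern:
            raise ValueError(f"marker {self.marker_id}: empty recognition pattern")
        object.__setattr__(self, "recognition_pattern", pattern)
        if self.amplicon is None and self.amplicon_length is None:
            raise ValueError(f"marker {self.marker_id}: need amplicon or amplicon_length")
        if self.amplicon is not None:
            amp = _check_iupac(self.amplicon, what=f"marker {self.marker_id} amplicon")
            if not amp:
                raise ValueError(f"marker {self.marker_id}: empty amplicon")
            object.__setattr__(self, "amplicon", amp)
            if self.amplicon_length is not None and self.amplicon_length != len(amp):
                raise ValueError(
                    f"marker {self.marker_id}: amplicon_length {self.amplicon_length} "
                    f"!= sequence length {len(amp)}")
            object.__setattr__(self, "amplicon_length", len(amp))
            if self.diagnostic_position is None:
                raise ValueError(
                    f"marker {self.marker_id}: diagnostic_position required with amplicon")
        if self.diagnostic_position is not None:
            if not 0 <= self.diagnostic_position < self.length:
                raise ValueError(
                    f"marker {self.marker_id}: diagnostic_position "
                    f"{self.diagnostic_position} outside amplicon [0, {self.length})")

    @property
    def length(self) -> int:
        assert self.amplicon_length is not None
        return self.amplicon_length

    @property
    def noncut_allele(self) -> str:
        a, b = self.alleles
        return b if self.cut_allele == a else a

    def with_amplicon(self, sequence: str) -> "MarkerDef":
        """Attach an amplicon sequence (e.g. loaded from FASTA)."""
        return replace(self, amplicon=sequence, amplicon_length=None)


@dataclass(frozen=True)
class FieldSite:
    """An experimental paddy field with its soil Cd status."""

    field_id: str
    soil_cd: float  # mg kg^-1
    soil_ph: float

    def __post_init__(self) -> None:
        if not self.field_id:
            raise ValueError("field_id must be non-empty")
        if not self.soil_cd > 0:
            raise ValueError(f"field {self.field_id}: soil_cd must be > 0")
        if not 0 < self.soil_ph < 14:
            raise ValueError(f"field {self.field_id}: soil_ph must lie in (0, 14)")

    @property
    def soil_cd_limit(self) -> float:
        """Applicable acidic-soil Cd screening limit for this pH."""
        return (SOIL_CD_LIMIT_PH_BELOW_5_5 if self.soil_ph < 5.5
                else SOIL_CD_LIMIT_PH_5_5_TO_6_5)


@dataclass(frozen=True)
class CdMeasurement:
    """Grain Cd concentration for one cultivar x field x replicate plot."""

    cultivar_id: str
    field_id: str
    replicate: int
    grain_cd: float  # mg kg^-1

    def __post_init__(self) -> None:
        if not self.cultivar_id or not self.field_id:
            raise ValueError("cultivar_id and field_id must be non-empty")
        if self.replicate < 1:
            raise ValueError(f"{self.cultivar_id}/{self.field_id}: replicate must be >= 1")
        if not (isinstance(self.grain_cd, (int, float)) and math.isfinite(self.grain_cd)):
            raise ValueError(f"{self.cultivar_id}/{self.field_id}: grain_cd must be finite")
        if self.grain_cd < 0:
            raise ValueError(
                f"{self.cultivar_id}/{self.field_id}: negative grain_cd {self.grain_cd}")


@dataclass(frozen=True)
class GenotypeCall:
    """Allele class of one cultivar at one marker (``HET``/``.`` allowed)."""

    cultivar_id: str
    marker_id: str
    allele: str

    def __post_init__(self) -> None:
        if not self.cultivar_id or not self.marker_id:
            raise ValueError("cultivar_id and marker_id must be non-empty")
        if not self.allele:
            raise ValueError(f"{self.cultivar_id}@{self.marker_id}: empty allele")


# --- TSV plumbing ----------------------------------------------------------

_MARKER_COLUMNS = ["marker_id", "alleles", "enzyme_name", "recognition_pattern",
                   "diagnostic_position", "cut_allele", "low_cd_allele",
                   "amplicon", "amplicon_length"]
_PHENOTYPE_COLUMNS = ["cultivar", "field", "replicate", "grain_cd"]
_GENOTYPE_COLUMNS = ["cultivar", "marker", "allele"]
_FIELD_COLUMNS = ["field", "soil_cd", "soil_ph"]


def _read_rows(path: str | Path, required: Sequence[str]):
    """Yield (line_number, {column: value}) for each data row of a TSV file."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableError("empty file (missing header)", path=path, line=1)
        header = [h.strip() for h in header]
        missing = [c for c in required if c not in header]
        if missing:
            raise TableError(f"missing required column(s) {missing}", path=path, line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise TableError(
                    f"expected {len(header)} fields, found {len(row)}",
                    path=path, line=lineno)
            yield lineno, dict(zip(header, (cell.strip() for cell in row)))


def _parse_number(raw: str, *, path, line, column, kind=float):
    try:
        return kind(raw)
    except ValueError:
        raise TableError(f"non-numeric value {raw!r}", path=path, line=line,
                         column=column) from None


def read_marker_table(path: str | Path) -> list[MarkerDef]:
    """Read a marker-definition TSV into validated :class:`MarkerDef` records.

    Columns: ``marker_id``, ``alleles`` (comma-separated pair),
    ``enzyme_name``, ``recognition_pattern``, ``diagnostic_position``,
    ``cut_allele``, ``low_cd_allele``, ``amplicon``, ``amplicon_length``;
    ``.`` marks an absent optional value.
    """
    markers: list[MarkerDef] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, _MARKER_COLUMNS):
        marker_id = row["marker_id"]
        if marker_id in seen:
            raise TableError(f"duplicate marker_id {marker_id!r}", path=path,
                             line=lineno, column="marker_id")
        seen.add(marker_id)
        alleles = tuple(a.strip() for a in row["alleles"].split(",") if a.strip())
        amplicon = None if row["amplicon"] in ("", MISSING) else row["amplicon"]
        length = (None if row["amplicon_length"] in ("", MISSING)
                  else _parse_number(row["amplicon_length"], path=path, line=lineno,
                                     column="amplicon_length", kind=int))
        diag = (None if row["diagnostic_position"] in ("", MISSING)
                else _parse_number(row["diagnostic_position"], path=path, line=lineno,
                                   column="diagnostic_position", kind=int))
        try:
            markers.append(MarkerDef(
                marker_id=marker_id,
                alleles=alleles,  # type: ignore[arg-type]
                enzyme_name=row["enzyme_name"],
                recognition_pattern=row["recognition_pattern"],
                diagnostic_position=diag,
                cut_allele=row["cut_allele"],
                low_cd_allele=row["low_cd_allele"],
                amplicon=amplicon,
                amplicon_length=length,
            ))
        except ValueError as exc:
            raise TableError(str(exc), path=path, line=lineno) from None
    return markers


def write_marker_table(markers: Iterable[MarkerDef], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MARKER_COLUMNS)
        for m in markers:
            writer.writerow([
                m.marker_id, ",".join(m.alleles), m.enzyme_name,
                m.recognition_pattern,
                MISSING if m.diagnostic_position is None else m.diagnostic_position,
                m.cut_allele, m.low_cd_allele,
                MISSING if m.amplicon is None else m.amplicon,
                MISSING if m.amplicon_length is None else m.amplicon_length,
            ])


def read_phenotype_table(path: str | Path) -> list[CdMeasurement]:
    """Read a grain-Cd phenotype TSV (cultivar, field, replicate, grain_cd)."""
    records: list[CdMeasurement] = []
    seen: set[tuple[str, str, int]] = set()
    for lineno, row in _read_rows(path, _PHENOTYPE_COLUMNS):
        replicate = _parse_number(row["replicate"], path=path, line=lineno,
                                  column="replicate", kind=int)
        grain_cd = _parse_number(row["grain_cd"], path=path, line=lineno,
                                 column="grain_cd")
        key = (row["cultivar"], row["field"], replicate)
        if key in seen:
            raise TableError(f"duplicate measurement {key}", path=path, line=lineno)
        seen.add(key)
        try:
            records.append(CdMeasurement(row["cultivar"], row["field"],
                                         replicate, grain_cd))
        except ValueError as exc:
            raise TableError(str(exc), path=path, line=lineno, column="grain_cd") from None
    return records


def write_phenotype_table(measurements: Iterable[CdMeasurement],
                          path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PHENOTYPE_COLUMNS)
        for rec in measurements:
            writer.writerow([rec.cultivar_id, rec.field_id, rec.replicate,
                             repr(rec.grain_cd)])


def read_genotype_table(path: str | Path,
                        markers: Sequence[MarkerDef] | None = None) -> list[GenotypeCall]:
    """Read a genotype-call TSV; allele symbols are validated against
    ``markers`` when provided (``HET`` and ``.`` always pass)."""
    allele_sets = None
    if markers is not None:
        allele_sets = {m.marker_id: set(m.alleles) for m in markers}
    calls: list[GenotypeCall] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in _read_rows(path, _GENOTYPE_COLUMNS):
        key = (row["cultivar"], row["marker"])
        if key in seen:
            raise TableError(f"duplicate genotype call {key}", path=path, line=lineno)
        seen.add(key)
        allele = row["allele"]
        if allele_sets is not None and allele not in (HET, MISSING):
            if row["marker"] not in allele_sets:
                raise TableError(f"unknown marker {row['marker']!r}", path=path,
                                 line=lineno, column="marker")
            if allele not in allele_sets[row["marker"]]:
                raise TableError(
                    f"allele {allele!r} not in marker {row['marker']}'s allele set",
                    path=path, line=lineno, column="allele")
        calls.append(GenotypeCall(row["cultivar"], row["marker"], allele))
    return calls


def write_genotype_table(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_GENOTYPE_COLUMNS)
        for call in calls:
            writer.writerow([call.cultivar_id, call.marker_id, call.allele])


def read_field_table(path: str | Path) -> list[FieldSite]:
    sites: list[FieldSite] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, _FIELD_COLUMNS):
        if row["field"] in seen:
            raise TableError(f"duplicate field {row['field']!r}", path=path,
                             line=lineno, column="field")
        seen.add(row["field"])
        try:
            sites.append(FieldSite(
                row["field"],
                _parse_number(row["soil_cd"], path=path, line=lineno, column="soil_cd"),
                _parse_number(row["soil_ph"], path=path, line=lineno, column="soil_ph"),
            ))
        except ValueError as exc:
            raise TableError(str(exc), path=path, line=lineno) from None
    return sites


def write_field_table(sites: Iterable[FieldSite], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_FIELD_COLUMNS)
        for site in sites:
            writer.writerow([site.field_id, repr(site.soil_cd), repr(site.soil_ph)])


# --- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``, uppercased and IUPAC-validated."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise TableError(f"duplicate FASTA id {record.id!r}", path=path)
        seq = str(record.seq).upper()
        for i, base in enumerate(seq):
            if base not in IUPAC_DNA:
                raise TableError(
                    f"record {record.id!r}: non-IUPAC character {base!r} at position {i}",
                    path=path)
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
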