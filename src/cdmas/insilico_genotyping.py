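"""In-silico CAPS/dCAPS assay: site scanning, digestion, allele calling.

Emulates the wet-lab genotyping workflow — PCR amplicon, restriction digest,
band pattern on an agarose gel — so that genotype calls can be produced and
stress-tested without chromatograms or gel images. A CAPS/dCAPS assay turns a
SNP into a presence/absence difference in an enzyme recognition site: the
*cut* allele's amplicon is cleaved into diagnostic fragments, the alternative
allele yields the intact amplicon, and a mixed template shows the union of
both band patterns.

The gel has finite resolution: band patterns whose distinguishing fragments
differ by less than :class:`ResolvabilityPolicy.min_fragment_separation`
cannot be told apart and the call is ``AMBIGUOUS``. This mirrors the known
weakness of gel-resolved dCAPS assays for heterozygous material; setting the
separation to 0 models capillary-style sizing and disables the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .tabular_io import HET, IUPAC_DNA, IUPAC_SETS, MISSING, GenotypeCall, MarkerDef

__all__ = [
    "AMBIGUOUS",
    "DigestResult",
    "ResolvabilityPolicy",
    "find_recognition_sites",
    "digest",
    "validate_assay",
    "predict_digest",
    "simulate_bands",
    "call_allele",
    "call_panel",
]

AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class DigestResult:
    """Predicted digest of one allele's amplicon.

    ``fragment_lengths`` are descending (gel order, largest band first) and
    always sum to the amplicon length; a digest with no cuts is the single
    intact band.
    """

    marker_id: str
    amplicon_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.fragment_lengths) != self.amplicon_length:
            raise ValueError(
                f"{self.marker_id}: fragments sum to {sum(self.fragment_lengths)}, "
                f"not amplicon length {self.amplicon_length}")
        if len(self.fragment_lengths) != len(self.cut_positions) + 1:
            raise ValueError(f"{self.marker_id}: fragment/cut count mismatch")
        if list(self.fragment_lengths) != sorted(self.fragment_lengths, reverse=True):
            raise ValueError(f"{self.marker_id}: fragments must be descending")


@dataclass(frozen=True)
class ResolvabilityPolicy:
    """Gel-resolution floor for distinguishing band patterns (bp)."""

    min_fragment_separation: float = 20.0

    def __post_init__(self) -> None:
        if self.min_fragment_separation < 0:
            raise ValueError("min_fragment_separation must be >= 0")


def _validate_iupac(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = next((i for i, b in enumerate(seq) if b not in IUPAC_DNA), None)
    if bad is not None:
        raise ValueError(f"{what}: non-IUPAC character {seq[bad]!r} at position {bad}")
    return seq


def _matches_at(sequence: str, pattern: str, offset: int) -> bool:
    # A window matches when every sequence base is compatible with the
    # pattern symbol: the base's IUPAC set is contained in the symbol's set.
    for p, s in zip(pattern, sequence[offset:offset + len(pattern)]):
        if not IUPAC_SETS[s] <= IUPAC_SETS[p]:
            return False
    return True


def find_recognition_sites(sequence: str, pattern: str) -> list[int]:
    """All 0-based offsets where ``pattern`` matches ``sequence``.

    The pattern is scanned on the given strand and, via its reverse
    complement, on the opposite strand; offsets are reported on the given
    strand. Overlapping matches are all returned. Palindromic Type II sites
    make the reverse scan a no-op.
    """
    sequence = _validate_iupac(sequence, "sequence")
    pattern = _validate_iupac(pattern, "pattern")
    if not pattern:
        raise ValueError("empty recognition pattern")
    if len(pattern) > len(sequence):
        return []
    rc = reverse_complement(pattern)
    hits = set()
    for offset in range(len(sequence) - len(pattern) + 1):
        if _matches_at(sequence, pattern, offset) or _matches_at(sequence, rc, offset):
            hits.add(offset)
    return sorted(hits)


def digest(amplicon_length: int, cut_offsets: Sequence[int]) -> list[int]:
    """Fragment lengths (descending) from cutting at the given offsets.

    Offsets are strictly ascending, strictly inside ``(0, amplicon_length)``;
    fragments are the consecutive differences of ``[0, *offsets, length]``,
    so they always sum to the amplicon length.
    """
    if amplicon_length <= 0:
        raise ValueError("amplicon_length must be positive")
    offsets = list(cut_offsets)
    if offsets != sorted(set(offsets)):
        raise ValueError("cut offsets must be strictly ascending")
    for off in offsets:
        if not 0 < off < amplicon_length:
            raise ValueError(f"cut offset {off} outside (0, {amplicon_length})")
    bounds = [0, *offsets, amplicon_length]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(fragments, reverse=True)


def validate_assay(marker: MarkerDef) -> tuple[list[int], list[int]]:
    """Check that a marker is a workable CAPS/dCAPS assay.

    Requires an amplicon whose recognition sites include at least one
    *diagnostic* site spanning the polymorphic base — the site the
    alternative allele destroys. Non-diagnostic sites are cut in both
    alleles (constitutive background bands). Returns
    ``(diagnostic_site_starts, constitutive_site_starts)``.
    """
    if marker.amplicon is None:
        raise ValueError(f"marker {marker.marker_id}: no amplicon sequence; "
                         "in-silico digestion needs the cut allele's amplicon")
    assert marker.diagnostic_position is not None
    sites = find_recognition_sites(marker.amplicon, marker.recognition_pattern)
    plen = len(marker.recognition_pattern)
    diagnostic = [s for s in sites
                  if s <= marker.diagnostic_position < s + plen]
    constitutive = [s for s in sites if s not in diagnostic]
    if not diagnostic:
        raise ValueError(
            f"marker {marker.marker_id}: no recognition site spans "
            f"diagnostic_position {marker.diagnostic_position}")
    if any(s == 0 for s in sites):
        raise ValueError(
            f"marker {marker.marker_id}: recognition site at amplicon start; "
            "cut at fragment boundary is not representable")
    return diagnostic, constitutive


def predict_digest(marker: MarkerDef, allele: str) -> DigestResult:
    """Predicted band pattern for one allele of the assay.

    The cut allele is cleaved at every site; the alternative allele retains
    the diagnostic site(s) uncut and is cleaved only at constitutive sites.
    """
    diagnostic, constitutive = validate_assay(marker)
    if allele == marker.cut_allele:
        offsets = sorted(diagnostic + constitutive)
    elif allele in marker.alleles:
        offsets = sorted(constitutive)
    else:
        raise ValueError(f"marker {marker.marker_id}: unknown allele {allele!r}")
    return DigestResult(
        marker_id=marker.marker_id,
        amplicon_length=marker.length,
        cut_positions=tuple(offsets),
        fragment_lengths=tuple(digest(marker.length, offsets)),
    )


def simulate_bands(marker: MarkerDef, true_genotype: str) -> list[int]:
    """Band multiset a gel would show for a true genotype (``HET`` = union)."""
    if true_genotype == HET:
        cut = predict_digest(marker, marker.cut_allele).fragment_lengths
        uncut = predict_digest(marker, marker.noncut_allele).fragment_lengths
        return sorted([*cut, *uncut], reverse=True)
    return list(predict_digest(marker, true_genotype).fragment_lengths)


def _distinguishable(p: Iterable[int], q: Iterable[int], sep: float) -> bool:
    """True when two band patterns can be told apart at gel resolution
    ``sep``: some *visible* band in one pattern sits >= sep away from every
    visible band of the other. Fragments shorter than ``sep`` run off the
    gel and are invisible — the reason small dCAPS size shifts cannot be
    resolved on agarose."""
    pb = {b for b in p if b >= sep}
    qb = {b for b in q if b >= sep}
    return (any(all(abs(b - o) >= sep for o in qb) for b in pb)
            or any(all(abs(b - o) >= sep for o in pb) for b in qb))


def call_allele(observed_fragments: Sequence[int], marker: MarkerDef,
                policy: ResolvabilityPolicy = ResolvabilityPolicy()) -> str:
    """Call the allele class from an observed fragment pattern.

    Matches the observed multiset against the cut allele's digest, the
    intact (non-cut) pattern, and their union (heterozygote). A match whose
    pattern is not gel-distinguishable from some other candidate pattern is
    reported ``AMBIGUOUS``; so is a pattern matching no candidate.
    """
    observed = sorted(int(f) for f in observed_fragments)
    if not observed or any(f <= 0 for f in observed):
        raise ValueError("observed fragments must be positive and non-empty")
    total = sum(observed)
    length = marker.length
    if total not in (length, 2 * length):
        raise ValueError(
            f"marker {marker.marker_id}: fragments sum to {total}, expected "
            f"{length} (single template) or {2 * length} (mixed template)")
    cut = sorted(predict_digest(marker, marker.cut_allele).fragment_lengths)
    uncut = sorted(predict_digest(marker, marker.noncut_allele).fragment_lengths)
    het = sorted([*cut, *uncut])
    candidates = {
        marker.cut_allele: cut,
        marker.noncut_allele: uncut,
        HET: het,
    }
    sep = policy.min_fragment_separation
    for outcome, pattern in candidates.items():
        if observed == pattern:
            others = [p for o, p in candidates.items() if o != outcome and p != pattern]
            if sep > 0 and any(not _distinguishable(pattern, other, sep)
                               for other in others):
                return AMBIGUOUS
            return outcome
    return AMBIGUOUS


def call_panel(markers: Sequence[MarkerDef],
               true_genotypes: Iterable[GenotypeCall],
               policy: ResolvabilityPolicy = ResolvabilityPolicy()) -> list[GenotypeCall]:
    """Re-call a panel's genotypes through the simulated assay.

    Each true genotype is rendered to its band pattern and called back;
    ``AMBIGUOUS`` outcomes become missing calls (``.``), as an unreadable
    gel lane would be scored.
    """
    by_id: Mapping[str, MarkerDef] = {m.marker_id: m for m in markers}
    out: list[GenotypeCall] = []
    for g in true_genotypes:
        marker = by_id.get(g.marker_id)
        if marker is None:
            raise ValueError(f"genotype references unknown marker {g.marker_id!r}")
        if g.allele == MISSING:
            out.append(g)
            continue
        bands = simulate_bands(marker, g.allele)
        called = call_allele(bands, marker, policy)
        out.append(GenotypeCall(g.cultivar_id, g.marker_id,
                                MISSING if called == AMBIGUOUS else called))
    return out
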