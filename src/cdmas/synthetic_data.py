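"""Synthetic rice cultivar panels with known genotype-phenotype structure.

Real per-cultivar screening data sit in a non-machine-readable appendix, so
every pipeline stage is exercised on generated panels that carry the same
statistical structure: a handful of diagnostic SNP markers with rare low-Cd
alleles, two field environments with strong main effects, genotype x field
interaction, and plot-replicate noise.

Grain Cd is generated log-normally — concentrations are positive and
right-skewed, with observed panels spanning up to ~17-fold between extreme
cultivars:

    log Cd[i, f, r] = baseline + sum_m effect_m * lowallele[i, m]
                      + field_effect[f] + gxe[i, f] + noise[i, f, r]

Alleles are drawn independently across markers at the configured low-allele
frequencies (no linkage is modelled; a joint-haplotype option plants exact
multi-locus class structures instead). The ground truth — allele vectors,
expected (noise-free) log Cd per cultivar and field, and which cultivars are
expected stably low — is returned alongside the tables so tests can check
recovery.

Two presets mirror the two screening seasons: ``EARLY`` (59 cultivars, 3
markers, fields A/B, grain Cd spanning roughly 0.03-0.5 mg kg^-1 with a
minority of cultivars under the 0.2 mg kg^-1 limit) and ``LATE`` (37
cultivars, 2 markers, fields C/D, 0.26-1.44 mg kg^-1, no cultivar under the
limit). Marker assays in the presets use toy amplicon sequences constructed
around an EcoRI site — synthetic stand-ins, not the published assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tabular_io import (
    GRAIN_CD_LIMIT,
    CdMeasurement,
    FieldSite,
    GenotypeCall,
    MarkerDef,
)

__all__ = [
    "MarkerModel",
    "PanelConfig",
    "GroundTruth",
    "SyntheticPanel",
    "EARLY",
    "LATE",
    "PRESET_FIELD_SITES",
    "generate_panel",
    "preset",
    "toy_marker_def",
]

EARLY = "EARLY"
LATE = "LATE"

#: Field metadata for the preset panels: soil Cd (mg kg^-1) and pH of the
#: four acidic paddy sites the presets emulate.
PRESET_FIELD_SITES: dict[str, FieldSite] = {
    "A": FieldSite("A", 0.48, 5.13),
    "B": FieldSite("B", 0.67, 5.61),
    "C": FieldSite("C", 0.78, 5.45),
    "D": FieldSite("D", 0.69, 5.76),
}


@dataclass(frozen=True)
class MarkerModel:
    """Generative model of one marker: low-allele frequency and its
    additive effect on log grain Cd (negative = protective)."""

    marker_id: str
    low_allele_freq: float
    effect: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_allele_freq <= 1:
            raise ValueError(f"{self.marker_id}: frequency outside [0, 1]")


@dataclass(frozen=True)
class PanelConfig:
    """Full specification of a synthetic cultivar panel."""

    n_cultivars: int
    field_ids: tuple[str, ...]
    markers: tuple[MarkerModel, ...]
    baseline_log_cd: float
    field_effects: dict[str, float]
    gxe_sd: float
    noise_sd: float
    n_replicates: int = 3
    seed: int = 0
    miscall_rate: float = 0.0
    #: optional joint haplotypes: [(allele-is-low vector, cultivar count), ...]
    #: summing to n_cultivars; overrides independent allele draws.
    haplotypes: tuple[tuple[tuple[bool, ...], int], ...] | None = None
    threshold: float = GRAIN_CD_LIMIT
    cultivar_prefix: str = "cv"

    def __post_init__(self) -> None:
        if self.n_cultivars < 1 or self.n_replicates < 1:
            raise ValueError("n_cultivars and n_replicates must be >= 1")
        if len(self.field_ids) < 1 or len(set(self.field_ids)) != len(self.field_ids):
            raise ValueError("field_ids must be non-empty and unique")
        if not self.markers:
            raise ValueError("at least one marker required")
        if set(self.field_effects) != set(self.field_ids):
            raise ValueError("field_effects must cover exactly field_ids")
        if self.gxe_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.miscall_rate <= 1:
            raise ValueError("miscall_rate outside [0, 1]")
        if self.haplotypes is not None:
            if sum(c for _, c in self.haplotypes) != self.n_cultivars:
                raise ValueError("haplotype counts must sum to n_cultivars")
            for vec, _ in self.haplotypes:
                if len(vec) != len(self.markers):
                    raise ValueError("haplotype vector length != marker count")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    #: cultivar -> tuple of booleans, True where the low-Cd allele was planted
    allele_vectors: dict[str, tuple[bool, ...]]
    #: (cultivar, field) -> expected log grain Cd (noise-free, gxe included)
    expected_log_cd: dict[tuple[str, str], float]
    #: cultivars whose expected Cd is below the threshold in every field
    stable_low: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticPanel:
    markers: tuple[MarkerDef, ...]
    fields: tuple[FieldSite, ...]
    genotypes: tuple[GenotypeCall, ...]
    measurements: tuple[CdMeasurement, ...]
    ground_truth: GroundTruth


# toy amplicon scaffold: unique EcoRI site, no spurious GAATTC on either
# strand (the site is palindromic, so one check suffices)
_TOY_PREFIX = ("ACGGTCCA" * 10)[:80]
_TOY_SUFFIX = ("TGCAGTCA" * 15)[:114]
_TOY_SITE = "GAATTC"
assert _TOY_SITE not in _TOY_PREFIX + _TOY_SUFFIX


def toy_marker_def(marker_id: str) -> MarkerDef:
    """A synthetic CAPS assay for simulation fixtures.

    200-bp toy amplicon with a single EcoRI site at offset 80; the low-Cd
    allele ('T') carries the site, the alternative allele ('C') destroys
    it. Not a published assay — a stand-in with the right structure.
    """
    amplicon = _TOY_PREFIX + _TOY_SITE + _TOY_SUFFIX
    return MarkerDef(
        marker_id=marker_id,
        alleles=("T", "C"),
        enzyme_name="EcoRI",
        recognition_pattern=_TOY_SITE,
        diagnostic_position=82,
        cut_allele="T",
        low_cd_allele="T",
        amplicon=amplicon,
    )


def _draw_alleles(config: PanelConfig, rng: np.random.Generator) -> list[tuple[bool, ...]]:
    if config.haplotypes is not None:
        vectors: list[tuple[bool, ...]] = []
        for vec, count in config.haplotypes:
            vectors.extend([tuple(vec)] * count)
        return vectors
    draws = rng.random((config.n_cultivars, len(config.markers)))
    freqs = np.array([m.low_allele_freq for m in config.markers])
    return [tuple(bool(b) for b in row) for row in draws < freqs]


def generate_panel(config: PanelConfig,
                   seed: int | None = None) -> SyntheticPanel:
    """Generate genotype calls, Cd measurements and ground truth.

    Deterministic given (config, seed); ``seed`` defaults to
    ``config.seed``. Genotype calls are the planted alleles, optionally
    corrupted by a flat per-call miscall rate (allele flipped).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    width = len(str(config.n_cultivars))
    cultivars = [f"{config.cultivar_prefix}{i + 1:0{width}d}"
                 for i in range(config.n_cultivars)]
    marker_defs = tuple(toy_marker_def(m.marker_id) for m in config.markers)

    vectors = _draw_alleles(config, rng)
    allele_vectors = dict(zip(cultivars, vectors))

    genotypes: list[GenotypeCall] = []
    for cultivar, vec in allele_vectors.items():
        for mdef, is_low in zip(marker_defs, vec):
            if config.miscall_rate and rng.random() < config.miscall_rate:
                is_low = not is_low
            high_allele = next(a for a in mdef.alleles if a != mdef.low_cd_allele)
            genotypes.append(GenotypeCall(
                cultivar, mdef.marker_id,
                mdef.low_cd_allele if is_low else high_allele))

    effects = np.array([m.effect for m in config.markers])
    gxe = rng.normal(0.0, config.gxe_sd,
                     (config.n_cultivars, len(config.field_ids)))
    expected_log: dict[tuple[str, str], float] = {}
    measurements: list[CdMeasurement] = []
    for i, cultivar in enumerate(cultivars):
        genetic = config.baseline_log_cd + float(
            effects @ np.array(allele_vectors[cultivar], dtype=float))
        for j, field_id in enumerate(config.field_ids):
            mu = genetic + config.field_effects[field_id] + float(gxe[i, j])
            expected_log[(cultivar, field_id)] = mu
            noise = rng.normal(0.0, config.noise_sd, config.n_replicates)
            for r in range(config.n_replicates):
                measurements.append(CdMeasurement(
                    cultivar, field_id, r + 1, float(math.exp(mu + noise[r]))))

    stable = tuple(sorted(
        c for c in cultivars
        if all(math.exp(expected_log[(c, f)]) < config.threshold
               for f in config.field_ids)))
    sites = tuple(PRESET_FIELD_SITES.get(f, FieldSite(f, 0.5, 5.5))
                  for f in config.field_ids)
    return SyntheticPanel(
        markers=marker_defs,
        fields=sites,
        genotypes=tuple(genotypes),
        measurements=tuple(measurements),
        ground_truth=GroundTruth(allele_vectors, expected_log, stable),
    )


def preset(name: str, seed: int = 0) -> PanelConfig:
    """Preset panel configurations for the two screening seasons.

    ``EARLY``: 59 cultivars x fields A/B x 3 replicates; three markers with
    rare protective alleles (frequencies 2/59, 1/59, 13/59; log-scale
    effects -1.6, -1.5, -0.35). ``LATE``: 37 cultivars x fields C/D x 3
    replicates; two markers (1/37 with a weak -0.35 effect; 34/37 with no
    effect — a marker whose "low" allele is common but uninformative), with
    a higher baseline so no cultivar is expected below the 0.2 mg kg^-1
    limit.
    """
    if name == EARLY:
        return PanelConfig(
            n_cultivars=59,
            field_ids=("A", "B"),
            markers=(
                MarkerModel("LCd-41", 2 / 59, -1.0),
                MarkerModel("CAL1", 1 / 59, -0.9),
                MarkerModel("LCd-38", 13 / 59, -0.35),
            ),
            baseline_log_cd=math.log(0.24),
            field_effects={"A": 0.0, "B": -0.05},
            gxe_sd=0.26,
            noise_sd=0.10,
            seed=seed,
        )
    if name == LATE:
        return PanelConfig(
            n_cultivars=37,
            field_ids=("C", "D"),
            markers=(
                MarkerModel("CAL1", 1 / 37, -0.35),
                MarkerModel("LCd-31", 34 / 37, 0.0),
            ),
            baseline_log_cd=math.log(0.45),
            field_effects={"C": 0.0, "D": 0.35},
            gxe_sd=0.22,
            noise_sd=0.08,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose {EARLY} or {LATE}")
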