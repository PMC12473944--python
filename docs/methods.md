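# Methods

## The screening problem

A cultivar panel is grown in several Cd-contaminated paddies with replicate
plots, grain Cd is measured per cultivar × field × replicate, and each
cultivar is genotyped at a small set of diagnostic SNP markers assayed as
CAPS/dCAPS restriction digests. The analysis asks how well single markers
and combined multi-locus genotypes predict which cultivars stay below the
food-safety threshold of 0.2 mg kg⁻¹ grain Cd (GB 2762-2022), and how the
phenotypic variance splits between genotype, field and their interaction.

## In-silico CAPS/dCAPS assay

A marker is defined by the cut allele's amplicon, an enzyme recognition
pattern (IUPAC), and the 0-based offset of the polymorphic base. The assay
is valid when at least one recognition site spans that base (the diagnostic
site); any other sites are constitutive and cut in both alleles. The
engineered dCAPS mismatch is assumed already embedded in the supplied
amplicon — assay design itself is out of scope, the assay definition is the
input. Patterns are scanned on the given strand and, via the
reverse-complement pattern, on the opposite strand; overlapping matches are
all reported. A pattern longer than the sequence simply has no matches.

Digestion is purely arithmetic: cutting at strictly ascending offsets in
`(0, L)` yields fragments that are consecutive differences of
`[0, offsets…, L]`, reported in descending (gel) order; their sum is always
the amplicon length, a conservation invariant tested on random cut sets.

Allele calling matches an observed fragment multiset against three
candidate patterns — cut-allele digest, intact non-cut amplicon, and their
union (heterozygote; fragment sum 2L). Gel realism enters through a single
parameter, `min_fragment_separation` (default 20 bp): fragments shorter
than it run off the gel and are invisible, and two patterns are
distinguishable only if some visible band of one lies at least that far
from every visible band of the other. A matched pattern that cannot be
distinguished from a competing candidate is returned `AMBIGUOUS` (mapped to
a missing call at the panel level), which reproduces the known failure mode
of gel-resolved dCAPS assays on small size shifts and on heterozygotes.
Setting the separation to 0 models capillary sizing and disables the
ambiguity entirely. Heterozygous calls are mapped to the high-Cd class by
default — conservative for food safety — with a missing-call option, since
inbred screening panels give no empirical rule to copy.

## Phenotype classification

Classification operates on the replicate-mean grain Cd per cultivar and
field, because accuracies are tabulated per cultivar and group means are
reported over plot replicates. LOW is strictly `mean < threshold`; the
boundary value is HIGH. A cultivar LOW in every field is a stably low
accumulator. Fold variation is `round(max/min)` half away from zero;
exceedance is the fraction of cultivar means at or above the threshold
(exactly `1 − #LOW/n`, an identity under test); the cumulative frequency
curve is the empirical CDF over cultivar means.

## Marker prediction and accuracy

A single marker predicts LOW iff the cultivar carries its designated
low-Cd allele. A combined panel partitions cultivars by the ordered allele
vector; classes are named `Multi-LCL1, Multi-LCL2, …` (late season:
`Multi-CL…`) in ascending order of class mean grain Cd, so naming is
deterministic. Two labeling modes exist because published screens do not
state the combined rule explicitly:

- `STABLE_LOW` (default): a class is LOW iff its member-mean grain Cd is
  below the threshold in *every* field. This is the only rule consistent
  with published combined-panel genotype counts, which match the stably-low
  classes rather than any union or intersection of single-marker calls.
- `ALL_LOW_ALLELES`: LOW iff the vector carries the low allele at every
  marker; on a one-marker panel this is bit-for-bit the single-marker
  prediction (a tested equivalence).

Accuracy statistics are pure count arithmetic on the per-field confusion
table; the class-wise, overall and across-field mean accuracies satisfy the
weighted-average identity `overall = (n_H·acc_H + n_L·acc_L)/n` on
unrounded fractions. An empty genotype class has *undefined* (not zero)
class accuracy, displayed as `-` and excluded from means. Display rounding
is half-up to one decimal, applied after all arithmetic; the same
convention reconstructs integer correct-call counts from printed
percentages (`round(acc·n)`).

Three printed-value quirks are worth recording. Recomputing the late-season
CAL1 overall accuracy from its counts gives 36/37 = 97.3% where 97.2 is
printed; the early field-B fold variation computes as 0.48/0.03 = 16 where
17 is printed (presumably computed from unrounded concentrations); and the
late-season interaction effect share computes as 46.75 → 46.8% where 46.7
is printed. These are printed-rounding discrepancies in the source tables;
the package follows its own arithmetic and does not chase them.

## Variance models

The two-way ANOVA is fixed-effects with interaction, computed by
nested-model residual comparison on explicit design matrices
(`numpy.linalg.lstsq`; rank-deficient one-hot encodings are fine because
only projections are needed). On balanced data the decomposition is exact:
`SS_A + SS_B + SS_AB + SS_E = SS_total`. Unbalanced designs get sequential
(hierarchical) SS by default — mains before interaction — with a Type-III
option under sum-to-zero contrasts; tiny negative differences are clamped
to zero. p-values come from the upper tail of the F distribution and are
displayed to 3 decimals with a `<0.001` floor. The effect-share column is
`SS_effect / (SS_effect + SS_error)` — numerically a partial η², and the
only formula consistent with published effect-share percentages, whose
table footnote ("by total SS") it therefore deliberately does not follow.
Published ANOVA degrees of freedom for this design family are not
reconstructible from a two-field layout (a field df of 2 with two fields);
the package computes df from the data it is given and makes no attempt to
emulate those rows.

In the pipeline the marker factor is the binary LOW/HIGH combined-genotype
label; when that label is constant (e.g. a late-season panel with no
stably-low class) the genotype classes themselves are used as the factor,
otherwise the ANOVA would be degenerate.

Tukey HSD judges every pair against the studentized-range quantile at
(k, error df), with Tukey-Kramer standard errors for unequal n. SNK is the
stepwise variant: range-ordered means, span-r quantiles, and the step-down
protection rule that declares everything inside a non-significant range
non-significant. With equal group sizes SNK is never less powerful than
Tukey (tested over 100 seeds); at k = 2 both coincide with the pooled
two-sample t-test via q = √2·|t| (tested as an identity). Quantiles are
cached because `scipy.stats.studentized_range.ppf` is expensive. Letters
use the insert-and-absorb algorithm ordered by descending mean, so `a`
marks the highest-mean homogeneous set; the lettering invariant (share a
letter ⟺ not significantly different) is property-tested on random
matrices. α defaults to 0.05 throughout.

## Synthetic panels

The generator draws log grain Cd as
`baseline + Σ_m effect_m·[low allele at m] + field_effect_f + gxe_{i,f} +
noise_{i,f,r}`, exponentiated. The log-normal form reflects that grain Cd
is positive and right-skewed, with multi-fold spreads between extreme
cultivars. Alleles are independent Bernoulli draws per marker (no linkage
is modelled — none is documented for these loci); a joint-haplotype option
plants exact multi-locus class structures and exact stable-low counts for
tests. All randomness flows from one `numpy` generator seeded from the
config, so identical seeds give identical panels. An optional flat miscall
rate flips genotype calls. Ground truth (allele vectors, noise-free
expected log Cd per field, expected stably-low cultivars) is returned with
every panel.

Preset defaults (chosen analytically from the published panel structure,
then verified by Monte-Carlo; all effects on the log scale):

- `EARLY`: 59 cultivars × fields A/B × 3 replicates; baseline
  `log(0.24 mg kg⁻¹)`; field shift −0.05 (B); markers at low-allele
  frequencies 2/59, 1/59, 13/59 with effects −1.0, −0.9, −0.35;
  gxe_sd 0.26, plot noise_sd 0.10. This places per-field cultivar means
  within 0.02–0.6 mg kg⁻¹ in ≥95 of 100 seeds, a partial exceedance of the
  0.2 limit in every seed, and a roughly 7–11-fold spread. The two strong
  protective alleles were deliberately kept moderate: a cultivar carrying
  both must not fall below the 0.02 floor.
- `LATE`: 37 cultivars × fields C/D × 3 replicates; baseline
  `log(0.45 mg kg⁻¹)`; field shift +0.35 (D); a rare weak protective allele
  (1/37, −0.35) and a common inert "low" allele (34/37, effect 0 — a marker
  whose designated low allele is uninformative, driving its overall
  accuracy to the low-genotype prevalence); gxe_sd 0.22, noise_sd 0.08. No
  cultivar is expected below the limit; median exceedance across seeds
  is 100%.

Field metadata for the presets (soil Cd 0.48–0.78 mg kg⁻¹, pH 5.13–5.76)
describes acidic paddies above the GB 15618-2018 screening limits.

What the generator does *not* emulate: soil-chemistry covariates, spatial
field heterogeneity, linkage between loci, cultivar random effects beyond
the G×E term, and measurement error structure beyond i.i.d. log-scale
noise. Tests passing on these panels therefore demonstrate that the
*machinery* is correct under the stated generative model, not that any
particular real marker achieves the simulated accuracies.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only in error
  messages and file line numbers.
- Tables are TSV, UTF-8, one header row, `.` for missing; every writer's
  output is re-readable by the corresponding parser (round-trip tested).
- Display rounding is half-up (`decimal`), never banker's.
- Ties at the safety threshold classify HIGH (the LOW rule is strict).
- Degenerate inputs fail loudly with named locations: empty ANOVA cells
  name the cell, missing genotype calls name cultivar and marker, parser
  errors name file, line and column.
- The pipeline's outputs are timestamp-free so reruns are byte-identical;
  the manifest hashes the analysis config (not the output path) and each
  output file.
- Problem sizes in tests and the acceptance script (panels of 30–59
  cultivars, 100–200 Monte-Carlo seeds, 200–500 random property cases)
  were chosen to exercise every code path at comfortable statistical
  resolution.

## Known limitations

- The in-silico assay models fragment presence/absence and size, not band
  intensity, partial digestion or star activity.
- SNK's dominance over Tukey is guaranteed only for equal group sizes; with
  unequal n the harmonic-mean SE can reorder decisions.
- Sequential SS depend on factor order in unbalanced designs; the pipeline
  always puts the genotype factor first. Type-III is available but is not
  the default.
- The stably-low labeling of combined classes is an inference about how
  published combined-panel counts arise, not a documented rule; both modes
  are exposed so the choice is explicit.
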