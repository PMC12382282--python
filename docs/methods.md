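# Methods

This note documents the models, statistics and design choices behind
`umicall`: a toolkit for UMI- and duplex-assisted consensus calling of
ultra-deep targeted cell-free DNA (cfDNA) sequencing, stratified
background-error modelling, ultra-low-frequency monitored-variant calling,
limit-of-detection estimation and panel-aggregate molecular-residual-disease
(MRD) testing — validated end to end against a bundled cfDNA read simulator
with known truth.

## The problem

Circulating tumour DNA (ctDNA) typically makes up 0.01–1% of plasma cfDNA.
Detecting a variant at, say, 0.1% allele fraction requires distinguishing a
handful of true mutant reads from PCR and sequencing errors that occur at a
similar per-base rate (~10⁻³). Two ideas make this possible:

1. **Molecular consensus.** Every template molecule is tagged with a unique
   molecular identifier (UMI) pair before amplification. All PCR duplicates
   of one molecule (a *UMI family*) are collapsed into a consensus read;
   independent sequencing errors vote each other out. Because the two
   strands of one double-stranded template yield reads observing the UMI
   pair in swapped order (*reciprocal UMIs*), families covering both
   strands can form a *duplex consensus* (DC) that also cancels
   strand-specific and single-strand PCR errors. Families from one strand
   give a *simplex consensus* (SC); SC and DC together are the *mixed
   consensus* (MC).
2. **Stratified background testing.** Residual consensus errors are
   estimated per consensus quality level — UMI-family sizes 1, 2, 3 and
   ≥ 4 — and each monitored site is tested against that empirical noise
   floor rather than a fixed threshold.

## Consensus model

* **Family definition.** Reads group on identical fragment endpoints
  (chrom, start, end) plus a canonical UMI key built in template-plus
  order, so reciprocal pairs from the two strands map to one key with
  opposite strand labels. UMI sequencing errors are tolerated with an
  adjustable edit distance (edlib): 3 for the 16 bp combined fixed-pool
  scheme, 2 recommended for 10 bp combined random UMIs. Keys are processed
  in descending read-count order (ties lexicographic) as greedy cluster
  seeds; a key joins the first seed within distance. This is deterministic
  and, at distance 0, exactly exact-key hashing.
* **Voting.** Members of a family share fragment endpoints, so columns are
  positional; no realignment is needed (the simulator emits no indels, and
  reads with aberrant CIGARs would be caught by the discordance filter).
  Per column the majority base is emitted when its voter fraction is
  ≥ 75% (the boundary case 3/4 is kept — masking applies to *< 75%*),
  otherwise the column becomes `N`. Ties at ≤ 50% are resolved by base
  order before the concordance check, which then masks them anyway for any
  threshold above one half.
* **Joint quality** is the arithmetic mean of the base qualities agreeing
  with the consensus, rounded, capped at 93; masked columns carry quality 2.
* **Discordant members.** A read disagreeing with the family-wide column
  majority at more than `max_discordant_fraction` of positions (default
  0.05; exposed because the appropriate value depends on library chemistry)
  is removed and the vote repeated. A family whose members are all
  discordant yields no consensus.
* **Duplex rule.** Duplex families first build one consensus per strand and
  emit a base only where the strand consensuses agree; disagreement or a
  masked strand gives `N`. Per-strand-then-compare was chosen over a single
  pooled vote because it gives the stronger guarantee (a base must survive
  two independent votes); family size still counts duplicates from either
  strand summed, which is what the size strata refer to.

## Background error model

Pileups are built per family-size stratum from the consensus reads over the
target regions plus a configurable flank (60 bp by default, matching the
MRD background window). `N` bases and bases below a quality floor are
ignored. Background counts exclude: non-autosomal contigs (any contig not
named like X/Y/M/MT counts as autosomal), known germline and monitored
somatic positions, and positions where any alternate allele reaches 20% of
the **pooled** (all-strata) depth — a real variant contaminates every
stratum, so pooling is the right level for that judgement (config-exposed).
Rates can optionally be split by the six unordered nucleotide-change groups
(A-C, A-G, A-T, C-G, C-T, G-T); the group error counts partition the
overall errors exactly, while each position's depth contributes to the
three groups containing its reference base. Integer counts are retained so
downstream tests are exact. Indels are not counted in the substitution
background; an indel background is carried separately for indel calling.

## Variant test, Z, fold change, LOD

For each monitored site the included strata (default 2, 3, ≥ 4) are pooled
into a single 2×2 table — site (alt, other) vs background (error bases,
other bases), using the matching change group when enabled — and evaluated
with a one-sided Fisher's exact test for alt enrichment, computed as the
hypergeometric upper tail (identical to `fisher_exact(...,"greater")`, and
verified in the tests against exact rational-arithmetic enumeration). The
application only ever asks "more alt than noise", so a two-sided test would
merely penalize true variants. An alternative per-stratum test combined via
Fisher's method is available behind a flag. A variant is *called* when
alt reads ≥ 3 and p ≤ 0.05 (both configurable).

Supporting statistics: proportion Z = (VAF − e)/√(e(1−e)/N) and fold
change VAF/e, with a zero background rate floored at one error per total
background bases. The limit of detection is the smallest VAF v whose
conservatively rounded expected alt count k = ⌈vD⌉ both meets the
read-support floor and reaches p ≤ α; since p is monotone non-increasing
in k at fixed margins, the smallest admissible k is found by exact binary
search (equivalent to exhaustively scanning every k, which the tests
verify) and LOD = k/D. With zero background this reduces to the closed
form min_alt_reads/D — e.g. three reads at 3000× gives 0.1%.

No multiple-testing correction is applied to monitored-variant calling:
the panel is small and pre-specified. Large de novo panels would need one.

## MRD aggregation

Monitored variants whose VAF deviates more than three sample standard
deviations from the panel mean are excluded first (with ≤ 2 variants or
zero SD nothing is excluded). Mutant and wild-type consensus bases are then
pooled over the remaining target loci and compared, in a single 2×2 table
with a one-sided Fisher's exact test, to the non-reference/reference ratio
in the ± 60 bp flanking windows. Flanks have no designated alternate
allele, so all non-reference substitution bases serve as the error proxy;
overlapping windows are merged and monitored positions are excluded from
flanks. Two positivity rules are reported side by side because both appear
in practice without a canonical reconciliation: the default p ≤ α rule,
and a strict rule additionally requiring ≥ 3 individually called variants.
Excluded outliers stay visible (flagged) in the kinetics tables.

## The simulator

The generator produces the statistical structure the method assumes, with
defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| wild-type fragment length | N(167, 10) bp | nucleosome-protected cfDNA peak |
| ctDNA fragment length | N(145, 12) bp | tumour fragments concentrated at 100–150 bp |
| genome equivalents | 303 per target | haploid genomes per ng of input DNA |
| duplicates per strand | geometric, mean 3 | heavy right tail of PCR amplification; exercises all four family-size strata |
| duplex probability | 0.5 | puts the duplex consensus fraction in the 46–56% range reported for real libraries |
| sequencing error | 10⁻³ /base | typical Illumina substitution rate |
| polymerase error | 3×10⁻⁵ /base/duplication | heritable PCR errors; places the mixed-consensus background near the ~2×10⁻⁵ study condition |
| UMI error | 10⁻³ /base | UMI bases are sequenced bases |
| UMI scheme | fixed pool 32×8 bp (or random 5 bp) | the two commercial designs supported |

Polymerase errors are drawn per duplication event and inherited by all
descendants of that product: the founder copy of a strand propagates its
errors to the entire simplex family (so SC error ≈ polymerase rate), while
a duplex consensus requires the same coincidence on both strands (DC error
≈ rate², effectively zero at these scales). This is precisely the mechanism
behind the observed SC-vs-DC error gap. Quality scores are a constant Q30
baseline; errors are emitted at the stated rates regardless of quality,
since quality only feeds the joint-quality computation. Coordinates are
0-based half-open internally, converted only at I/O boundaries. Every
fragment is placed to cover its target's monitored site, so the per-site
consensus depth equals the genome-equivalent count minus families lost to
filters.

**What the simulator does not model** — and hence what passing tests do
not demonstrate about real data: GC and capture-efficiency bias, fragment
end motifs, indel spike-ins, strand-specific damage artefacts (e.g. 8-oxoG
or deamination asymmetries), mapping ambiguity and soft-clipping, and
inter-site coverage variation beyond sampling noise. Error-rate and
specificity results on simulation are therefore best-case floors, not
field performance claims.

## Problem sizes used in validation

The bundled test suite and the reproduction script size simulations to
keep a laptop-class run practical while retaining statistical power: the
low-VAF panel and wild-type specificity runs use 50 targets at 6500 genome
equivalents each (~5400× pooled consensus depth over strata ≥ 2, ~1.5
million raw reads, ~3×10⁷ consensus bases); the wild-type battery uses
three seeds at 1500 genome equivalents; property checks run on smaller
seeded replicates. The MRD type-I property is exercised at the
contingency-counts level (binomial error sampling feeding the same Fisher
routine), since hundreds of read-level replicates at full depth would add
nothing statistical to the same test.

## Numerical and degenerate-input choices

* Fisher p-values are clamped into (0, 1]; zero alt count returns exactly 1.
* A stratum with no usable background coverage is flagged and dropped from
  pooling with a warning; a site with zero pooled depth is reported
  uncalled with reason `no_coverage`.
* `proportion_z`/`fold_change` floor a zero background rate at one error
  per total background bases.
* Outlier exclusion uses the sample standard deviation (ddof = 1) and is
  skipped entirely for ≤ 2 variants or zero spread.
* Indel alleles are normalized to left-aligned VCF-style representation
  before testing; normalization is idempotent.
* Empty consensus input produces empty output plus a logged warning rather
  than an error, so pipelines fail at the stage that actually lacks data.

## Known limitations

* The de novo (panel-free) calling mode with a combined overdispersed
  error model is out of scope; only monitored (tumour-informed) sites are
  tested.
* No UMI whitelist correction: grouping never requires a UMI reference
  file, which is what makes both fixed-pool and random schemes work, but
  means a corrupted UMI pair within edit distance of another family can in
  principle be mis-assigned.
* Reads are modelled at fragment resolution (one record spanning the
  fragment, as with fully overlapping merged read pairs); split mates with
  an inner gap are not represented.
* CNVs, fusions and clonal-haematopoiesis filtering are out of scope.
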