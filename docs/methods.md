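# Methods

## Scope and data model

`varprio` re-prioritizes single-nucleotide variants and short indels in
already-sequenced, already-annotated rare-disease cohorts. It deliberately
begins *after* the upstream pipeline: variants arrive as per-family VCFs with
a gene symbol and consequence term per record (INFO/GENE, INFO/CSQ), assumed
left-aligned and normalized upstream. Multi-allelic sites are decomposed into
one record per alternate allele on read; each decomposed genotype counts
copies of its own alternate only. All coordinates are 1-based inclusive
(VCF convention); BED input is converted on read; `chr` prefixes are stripped
and the mitochondrial contig is normalized to `MT`. Hemizygous male-X and
mitochondrial calls are ploidy-1 with allele count in {0, 1}.

A deliberate convention runs through the whole engine: **a missing genotype
is unknown, never homozygous-reference**. Missing calls are excluded from
allele-frequency denominators, and an uncalled parent can never confirm a
de novo event. The alternative (missing ⇒ hom-ref) silently converts absence
of evidence into evidence and inflates de novo calls.

## The filter stack

The first-round preset is a pure conjunction over per-variant annotations:
population allele frequency < 0.01 (a variant absent from the population
catalogue is treated as frequency 0 — absence from gnomAD-scale data *is*
evidence of rarity), internal cohort frequency < 0.02, gene in the resolved
panel, a pathogenic/likely-pathogenic assertion, and at least one alternate
allele in the index case. Because it is a pure predicate, filter order cannot
affect the result, and tightening any threshold or shrinking the panel can
only shrink the surviving set; both properties are tested.

**Internal cohort frequency** is computed over one experiment per family (the
index): alt alleles / called alleles. Family deduplication stops a large
sequenced family from suppressing its own causal variant. The denominator
counts ploidy, so hemizygous calls contribute one allele.

**Assertion aggregation.** Multiple assertions for one variant collapse
deterministically and order-independently: unanimous values are kept,
discordant sets become `conflicting`, and the earliest P/LP year is retained.
Qualification for the pathogenicity filter is sensitivity-first: a variant
qualifies if *any* assertion is P/LP (configurable to require concordance).
The asserted condition string is carried to the report rather than matched
against the patient's disorder — clinical fit is judged by the human
reviewer downstream, and hard-coding disorder matching would silently drop
atypical presentations. Per-table version stamps are propagated into the
candidate-table header so every report pins its knowledge snapshot.

**Segregation annotates, it does not filter.** Reviewers see
inconsistent-segregation rows too (penetrance is imperfect and pedigrees are
often partial); a `segregation_filter` switch enables hard filtering for
stricter rounds. Rules for trios generalize to whatever relatives carry
called genotypes: affected relatives must carry compatibly, unaffected ones
must not (an `allow_reduced_penetrance` flag relaxes the unaffected-carrier
veto). A family with no informative relatives is unconstrained: every model
returns consistent with the reason recorded, matching the practice of
prioritizing singleton candidates without segregation evidence. The mosaic
flag (allelic fraction < 0.30) is annotation only.

**Compound heterozygotes.** With both parents genotyped, two heterozygous
index variants in one gene pair only in trans (one paternal-only, one
maternal-only by parental origin); without parents, all C(k,2) pairs are
reported phase-unknown. Statistical phasing is out of scope.

## Runs of homozygosity and consanguinity

ROH detection is tuned for sparse exome sites: a run must span ≥ 1 Mb
(`roh.min_length_bp`), contain ≥ 25 sites (`roh.min_sites`) and tolerate at
most 1 heterozygous call (`roh.max_het`). Only *informative* markers enter
the scan — diploid autosomal calls at sites with population AF in
[0.05, 0.95] — because a site where nearly everyone is homozygous-reference
says nothing about autozygosity; without this restriction the near-monomorphic
majority of exome sites produces ROH everywhere. Runs are found by a
leftmost-greedy scan (start at the first unconsumed homozygous site, extend
right while the het budget holds, trim to homozygous boundaries), which makes
segments non-overlapping and individually maximal; "all maximal windows"
cannot be simultaneously non-overlapping when windows straddle a shared het,
so the greedy definition is the one both the implementation and the test
oracle use. Two qualifying runs separated by more than `max_het` het calls
never merge.

F_ROH = Σ autosomal ROH length / autosome length, with consanguinity inferred
at F_ROH ≥ 0.03 (closer than second-cousin parental relatedness; configurable).
Calibration: offspring of first cousins (expected F = 1/16 = 0.0625) are
gene-dropped through the six-meiosis cousin loop with Poisson recombination
over a 30-chromosome, 100-Mb/chromosome genome (1 cM/Mb, informative sites
every 250 kb, MAF 0.3). Over 20 replicates the estimator's mean lands within
±0.02 of 0.0625; the residual downward bias is real and expected — tracts
shorter than the 25-site minimum are invisible. At the liberal 1 Mb / 25-site
setting, sparse-site noise also produces occasional spurious small ROH
(≈ 15% of synthetic non-consanguineous cases acquire F_ROH just above 0.03),
which is the price of a sensitivity-first threshold; true consanguineous
cases sit well above it.

**CNV cross-check.** A homozygous candidate overlapping a heterozygous
deletion call in the same person may be hemizygous, not homozygous; such rows
are flagged `suspect` (interval-tree point query; never filtered).

## Case status and summaries

Case decisions are event-sourced: the registry is exactly the replay of its
event log, so any state is auditable and reproducible. Solving a case
requires naming variant keys among the case's rows (named rows become
`solved`, the rest `rejected`); solved cases are skipped on later rounds
unless `--include-solved`. At summary time each case carries exactly one
status, with precedence solved > under evaluation > het-AR candidate >
unsolved, so the four statuses partition the analysed cases.

Derived statistics use half-up decimal rounding — means to 2 decimals,
percentages to 1. Published cohort tables of this kind mix rounding and
truncation (e.g. a 28.6% trio fraction printed as 28%), so recomputed
percentages can differ from printed ones by up to ±0.2 at one decimal.
Knowledge-recency binning histograms causative variants over
{≥2017, 2015–2016, 2010–2014, <2010, unknown} twice: by the gene's first
disease association and by the variant's first P/LP assertion.

## The synthetic cohort generator

The generator emulates the statistical structure the engine assumes, not
human genetics: a toy genome of two 10-Mb autosomes, a 5-Mb X and MT
(ROH logic stays cheap to exercise); 112 genes in 200-kb blocks (12 AD, 14
AR, 4 XL, 1 MT, 60 background) split into four network panels such that every
panel supports every inheritance model; a 4-level mini-ontology of 32 leaf
phenotype terms, two per disease gene. Defaults are the study conditions:
200 families mixed 28/68/4% trio/singleton/other, network weights
≈ 33/46/14/6%, 55.7% male probands, 1500 shared background sites with allele
frequencies log-uniform on [1e-5, 0.5] (so the frequency filters have bite),
genotypes drawn by Hardy–Weinberg with Mendelian transmission inside each
family, 1% missingness. Planted models default to 20% AD de novo, 15% AD
inherited, 10% AR homozygous, 8% AR homozygous-in-ROH (a ±1.5 Mb homozygous
flank is forced around the variant), 12% AR compound-het, 6% XL, 2% MT, 2%
mosaic (allelic fraction 0.05–0.25), 10% lone-het AR, 15% none; half of the
"none" families carry a decoy P/LP variant at population AF 0.05 that must
fail the rarity filter. Planted assertion years follow the published
knowledge-recency mix. Everything is deterministic under the seed, to the
byte.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: linkage disequilibrium and realistic site spacing,
sequencing artefacts beyond uniform missingness, annotation errors
(gene/consequence are always correct), population structure, and phenotype
noise beyond one random extra HPO term. Recall of planted variants is a
check of the engine's plumbing under its own assumptions, not a clinical
sensitivity estimate.

## Problem sizes and numerics

The test suite runs the full pipeline on a 200-family cohort (the study
scale) plus a 60-family fixture for per-module tests; a 60-family cohort is
the practical minimum at which a homozygous causative variant (2 of ~120
index alleles) stays under the 2% internal-frequency ceiling — below that,
the internal filter correctly removes planted homozygotes. Frequencies are
written with 6 significant digits and round-trip through the TSV at that
precision; all row ordering is deterministic (case id, then contig, position,
ref, alt with natural contig order). Thresholds compare strictly
(`af < cutoff`), so a variant at exactly 0.01 fails.

## Known limitations

No statistical phasing, no PLINK/LOD-style ROH scoring, no CNV calling, no
ACMG re-classification, no semantic phenotype similarity (on-the-fly panels
are set expansion over the ontology, not Exomiser-style ranking). The
candidate table's 28-column contract packs multi-valued annotations
(associations, verdicts, flags) into `key=value;...` strings — convenient
for a single distributable table, lossy for nothing, but not a relational
export.
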