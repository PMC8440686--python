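# varprio

Programmatic re-prioritization of rare known pathogenic variants in
undiagnosed rare-disease exome/genome cohorts.

## The problem

Most rare diseases are genetic, yet exome/genome sequencing leaves 40–80% of
cases without a molecular diagnosis. Knowledge moves on — hundreds of new
gene–disease associations and thousands of new pathogenic-variant assertions
are curated every year — so a case that was negative at first analysis may be
solvable today *from the data already produced*. Doing that by hand for
thousands of cases is what keeps reanalysis out of routine practice.

`varprio` is a scriptable engine for that reanalysis step. It consumes
pre-annotated per-family variant calls (VCF), pedigrees (PED), standardized
phenotype records (HPO/ORDO/OMIM, phenopacket-style JSON) and versioned
knowledge tables (pathogenicity assertions, population allele frequencies,
gene–disease associations with first-report years, constraint scores,
precomputed ACMG classes), applies a configurable filter stack per index
case, and emits a single candidate table for expert review, plus cohort
summary statistics. Cases are analysed sequentially; decisions (solved /
under evaluation / unsolved) flow back through a registry, and solved cases
are excluded from later rounds.

## The method

The first-round **"low-hanging fruit" preset** keeps a variant *v* for index
case *i* iff

```
AF_pop(v)      < 0.01      (population, gnomAD-style; absent ⇒ 0)
AF_internal(v) < 0.02      (cohort AF over one index per family)
gene(v)        ∈ panel(i)  (ERN-curated, explicit, or on-the-fly from HPO terms)
ClinVar-style assertion of v is pathogenic / likely pathogenic
index carries ≥ 1 alternate allele
```

Everything else **annotates rather than filters**: segregation verdicts under
AD (de novo / inherited), AR (homozygous / compound-het with parental-origin
phasing), X-linked, mitochondrial and mosaic models; run-of-homozygosity
(ROH) membership (runs ≥ 1 Mb, ≥ 25 informative sites, ≤ 1 het call);
consanguinity as F_ROH = Σ ROH length / autosome length (threshold 0.03); and
a cross-check of homozygous candidates against heterozygous-deletion CNV
calls that could fake homozygosity. Lone heterozygous hits in recessive-only
genes are flagged `het_AR_candidate` for follow-up. Causative variants are
binned by the year their gene (or the variant itself) entered the literature,
quantifying how much of the new yield is newly available knowledge.

A seedable synthetic-cohort generator (`varprio simulate`) emulates the
cohort structure the engine assumes — trio/singleton/other families, planted
causative variants under every supported model (including homozygous-in-ROH
and mosaic), matching knowledge tables and decoy variants — with a truth
table, so the whole pipeline is testable without patient data.

## Worked example

```
varprio simulate --seed 11 --families 60 --background-sites 800 --out demo
varprio reanalyse --config demo/config.yaml
# processed 60 cases (0 failed), 57 candidate rows -> demo/out
```

`demo/out/candidates.tsv` (28 fixed columns; excerpt):

```
case_id contig     pos gene genotype_index clinical_significance  af_external           status
FAM0001      1  311724 D003            0/1            pathogenic     0.001599        candidate
FAM0002      1 1383930 D013            0/1            pathogenic     0.000000 het_AR_candidate
FAM0003      2 1897362 D020            1/1            pathogenic     0.000198        candidate
FAM0004      2  412614 D006            0/1     likely_pathogenic     0.000029        candidate
```

FAM0002's row is a lone heterozygote in a recessive-disease gene — reported,
but flagged as insufficient on its own. `demo/out/summary.tsv` accounts for
the run per submitting network:

```
     ern  n_cases  n_trio  n_singleton  n_other  n_candidate_variants  n_cases_with_candidates  n_het_ar_cases  mean_candidates_per_case
  ITHACA       22       8           12        2                    21                       18               2                      1.17
     RND       28      11           17        0                    27                       25               3                      1.08
 euroNMD        8       2            6        0                     7                        7               1                      1.00
GENTURIS        2       2            0        0                     2                        2               0                      1.00
   TOTAL       60      23           35        2                    57                       52               6                      1.10
```

Tag a diagnosis and the case drops out of the next round:

```
varprio tag --registry demo/registry.json --case FAM0003 --decision solved \
    --variants 2:1897362:T:G --table demo/out/candidates.tsv
varprio reanalyse --config demo/config.yaml        # FAM0003 now skipped
```

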