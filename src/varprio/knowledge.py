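"""Knowledge tables: pathogenicity assertions, population and cohort allele
frequencies, gene-disease associations, constraint scores and pre-computed
ACMG classes, joined onto variant records.

The tables are TSV with fixed headers (see the ``_REQUIRED`` map below) and are
versioned: each file may carry a first line ``## version=<stamp>`` which is
propagated into the candidate-table header, mirroring how a production run
pins e.g. a ClinVar snapshot date.

Aggregation of conflicting assertions for one variant is deterministic and
order-independent. By default a variant *qualifies* as pathogenic/likely
pathogenic if ANY assertion for it is P/LP (sensitivity-first, since the
output is reviewed by humans); the stricter "all assertions concordant" rule
is available via ``plp_aggregation="concordant"`` in the filter config.

The internal cohort allele frequency is computed over one representative
experiment per family (the index) so a large sequenced family cannot suppress
its own causal variant; missing calls never enter the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .models_io import GenotypeCall, VariantRecord, normalize_contig

logger = logging.getLogger("varprio")

SIGNIFICANCE_VOCAB = {
    "pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "conflicting",
}
PLP = {"pathogenic", "likely_pathogenic"}
INHERITANCE_VOCAB = {"AD", "AR", "XL", "MT"}
ACMG_VOCAB = {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign"}

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class PathogenicityAssertion:
    significance: str
    condition: str = ""
    first_plp_year: Optional[int] = None

    def __post_init__(self):
        if self.significance not in SIGNIFICANCE_VOCAB:
            raise ValueError(f"unknown clinical significance {self.significance!r}")
        if (self.first_plp_year is not None) != (self.significance in PLP):
            raise ValueError("first_plp_year must be present iff significance is P/LP")


@dataclass(frozen=True)
class CollapsedAssertion:
    """Per-variant aggregate over possibly-conflicting assertions."""

    significance: str  # collapsed value (may be "conflicting")
    condition: str
    first_plp_year: Optional[int]
    any_plp: bool


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    gene: str
    omim_disease_id: str
    inheritance_mode: str
    first_association_year: Optional[int] = None

    def __post_init__(self):
        if self.inheritance_mode not in INHERITANCE_VOCAB:
            raise ValueError(f"unknown inheritance mode {self.inheritance_mode!r}")


@dataclass(frozen=True)
class ConstraintScore:
    gene: str
    pli: float
    oe: float

    def __post_init__(self):
        if not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI out of [0,1]: {self.pli}")
        if self.oe < 0:
            raise ValueError(f"o/e must be >= 0: {self.oe}")


@dataclass(frozen=True)
class AcmgAnnotation:
    predicted_class: str
    criteria: tuple[str, ...] = ()

    def __post_init__(self):
        if self.predicted_class not in ACMG_VOCAB:
            raise ValueError(f"unknown ACMG class {self.predicted_class!r}")


@dataclass
class KnowledgeBase:
    assertions: dict[VariantKey, CollapsedAssertion] = field(default_factory=dict)
    frequencies: dict[VariantKey, float] = field(default_factory=dict)
    gene2disease: dict[str, list[GeneDiseaseAssociation]] = field(default_factory=dict)
    constraint: dict[str, ConstraintScore] = field(default_factory=dict)
    acmg: dict[VariantKey, AcmgAnnotation] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def version_stamps(self) -> list[str]:
        return [f"{name} version={stamp}" for name, stamp in sorted(self.versions.items())]


_REQUIRED = {
    "assertions": ["contig", "pos", "ref", "alt", "significance", "condition", "first_plp_year"],
    "frequencies": ["contig", "pos", "ref", "alt", "af"],
    "gene2disease": ["gene", "omim_id", "inheritance", "first_year"],
    "constraint": ["gene", "pli", "oe"],
    "acmg": ["contig", "pos", "ref", "alt", "class", "criteria"],
}


def _read_table(path: Path, name: str) -> tuple[pd.DataFrame, Optional[str]]:
    version = None
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("##"):
        skip = 1
        if "version=" in first:
            version = first.split("version=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str, keep_default_na=False)
    for col in _REQUIRED[name]:
        if col not in df.columns:
            raise ValueError(f"{name} table {path} is missing mandatory column {col!r}")
    return df, version


def _variant_key(row) -> VariantKey:
    return (normalize_contig(row["contig"]), int(row["pos"]), row["ref"], row["alt"])


def collapse_assertions(assertions: Iterable[PathogenicityAssertion],
                        plp_wins: bool = False) -> CollapsedAssertion:
    """Collapse all assertions for one variant into a single record.

    Unanimous significance is kept as-is; discordant sets collapse to
    "conflicting" unless ``plp_wins`` is set, in which case the most severe
    P/LP value wins. The result depends only on the multiset of assertions,
    never on row order.
    """
    items = sorted(assertions, key=lambda a: (a.significance, a.condition, a.first_plp_year or 0))
    if not items:
        raise ValueError("no assertions to collapse")
    sigs = {a.significance for a in items}
    any_plp = bool(sigs & PLP)
    if len(sigs) == 1:
        significance = items[0].significance
    elif plp_wins and any_plp:
        significance = "pathogenic" if "pathogenic" in sigs else "likely_pathogenic"
    else:
        significance = "conflicting"
    plp_years = [a.first_plp_year for a in items if a.first_plp_year is not None]
    conditions = sorted({a.condition for a in items if a.condition})
    return CollapsedAssertion(
        significance=significance,
        condition="; ".join(conditions),
        first_plp_year=min(plp_years) if plp_years else None,
        any_plp=any_plp,
    )


def load_knowledge(paths: Mapping[str, str | Path], plp_wins: bool = False) -> KnowledgeBase:
    """Load and join the knowledge tables.

    ``paths`` maps table names (assertions, frequencies, gene2disease,
    constraint, acmg) to TSV files; any table may be omitted, in which case
    the corresponding lookups are empty ("never observed").
    """
    kb = KnowledgeBase()

    if "assertions" in paths:
        df, version = _read_table(Path(paths["assertions"]), "assertions")
        if version:
            kb.versions["assertions"] = version
        grouped: dict[VariantKey, list[PathogenicityAssertion]] = {}
        for _, row in df.iterrows():
            year = int(row["first_plp_year"]) if row["first_plp_year"] else None
            grouped.setdefault(_variant_key(row), []).append(
                PathogenicityAssertion(row["significance"], row["condition"], year)
            )
        kb.assertions = {k: collapse_assertions(v, plp_wins) for k, v in grouped.items()}

    if "frequencies" in paths:
        df, version = _read_table(Path(paths["frequencies"]), "frequencies")
        if version:
            kb.versions["frequencies"] = version
        for _, row in df.iterrows():
            af = float(row["af"])
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {af}")
            kb.frequencies[_variant_key(row)] = af

    if "gene2disease" in paths:
        df, version = _read_table(Path(paths["gene2disease"]), "gene2disease")
        if version:
            kb.versions["gene2disease"] = version
        for _, row in df.iterrows():
            assoc = GeneDiseaseAssociation(
                gene=row["gene"].upper(),
                omim_disease_id=row["omim_id"],
                inheritance_mode=row["inheritance"],
                first_association_year=int(row["first_year"]) if row["first_year"] else None,
            )
            kb.gene2disease.setdefault(assoc.gene, []).append(assoc)
        for gene in kb.gene2disease:
            kb.gene2disease[gene].sort(key=lambda a: (a.omim_disease_id, a.inheritance_mode))

    if "constraint" in paths:
        df, version = _read_table(Path(paths["constraint"]), "constraint")
        if version:
            kb.versions["constraint"] = version
        for _, row in df.iterrows():
            kb.constraint[row["gene"].upper()] = ConstraintScore(
                row["gene"].upper(), float(row["pli"]), float(row["oe"])
            )

    if "acmg" in paths:
        df, version = _read_table(Path(paths["acmg"]), "acmg")
        if version:
            kb.versions["acmg"] = version
        for _, row in df.iterrows():
            criteria = tuple(c for c in row["criteria"].split(",") if c)
            kb.acmg[_variant_key(row)] = AcmgAnnotation(row["class"], criteria)

    return kb


def internal_allele_frequency(index_genotypes: Iterable[GenotypeCall]) -> float:
    """Cohort allele frequency at one site over index-case genotypes only.

    af = alt allele count / called allele count; 0.0 when nothing is called.
    """
    alt = 0
    called = 0
    for gt in index_genotypes:
        if gt.is_missing:
            continue
        alt += gt.allele_count
        called += gt.ploidy
    return alt / called if called else 0.0


def cohort_internal_frequencies(
    cohort_index_genotypes: Mapping[VariantKey, list[GenotypeCall]]
) -> dict[VariantKey, float]:
    return {k: internal_allele_frequency(gts) for k, gts in cohort_index_genotypes.items()}


def annotate(variant: VariantRecord, kb: KnowledgeBase,
             af_internal: Optional[float] = None) -> VariantRecord:
    """Join knowledge fields onto a variant (in place; genotypes and
    coordinates are untouched).

    Variant-level tables join by exact (contig, pos, ref, alt); gene-level
    tables by gene symbol. A variant absent from the external frequency table
    gets ``af_external = 0.0``: absence from a population catalogue is
    treated as evidence of rarity.
    """
    key = variant.key
    assertion = kb.assertions.get(key)
    if assertion is not None:
        variant.clinical_significance = assertion.significance
        variant.condition = assertion.condition
        variant.first_plp_year = assertion.first_plp_year
        variant.is_plp = assertion.any_plp
    variant.af_external = kb.frequencies.get(key, 0.0)
    if af_internal is not None:
        variant.af_internal = af_internal
    gene = variant.gene.upper()
    assocs = kb.gene2disease.get(gene, [])
    variant.associations = tuple(assocs)
    years = [a.first_association_year for a in assocs if a.first_association_year is not None]
    variant.first_association_year = min(years) if years else None
    constraint = kb.constraint.get(gene)
    if constraint is not None:
        variant.pli = constraint.pli
        variant.oe = constraint.oe
    acmg = kb.acmg.get(key)
    if acmg is not None:
        variant.acmg_class = acmg.predicted_class
        variant.acmg_criteria = acmg.criteria
    return variant
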