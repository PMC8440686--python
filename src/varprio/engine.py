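"""The configurable filter stack and run orchestration.

The first-round "low-hanging fruit" preset keeps a variant for an index case
iff it is rare (external population AF < 0.01 and internal cohort AF < 0.02),
falls in the case's gene panel, carries a pathogenic / likely-pathogenic
assertion, and the index carries at least one alternate allele. Segregation
verdicts, compound-het pairing, ROH membership, consanguinity and the CNV
cross-check are attached as annotations — they inform the human reviewer, they
do not filter (a ``segregation_filter`` switch enables hard filtering for
later rounds). The surviving rows for all cases form a single candidate
table distributed for expert review; case-level decisions (solved / under
evaluation / unsolved) flow back through a persistent registry, and solved
cases are excluded from subsequent reanalysis rounds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from . import knowledge as kn
from . import inheritance as inh
from . import phenotype as ph
from .models_io import (
    CandidateRow,
    CnvCall,
    GenePanel,
    Pedigree,
    PhenotypeRecord,
    VariantRecord,
    read_candidate_table,
    read_cnv_bed,
    read_gene_panel,
    read_ped,
    read_phenotype_records,
    read_vcf,
    write_candidate_table,
)

logger = logging.getLogger("varprio")

CASE_STATUSES = ("solved", "under_evaluation", "het_AR_candidate", "unsolved")
YEAR_BINS = (">=2017", "2015-2016", "2010-2014", "<2010", "unknown")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (what the reported percentages use)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Filter-stack parameters; defaults are the low-hanging-fruit preset."""

    af_external_max: float = 0.01
    af_internal_max: float = 0.02
    require_plp: bool = True
    plp_aggregation: str = "any"  # "any" | "concordant"
    consequence_whitelist: Optional[set[str]] = None
    region_restriction: str = "none"  # "none" | "roh" | "custom"
    custom_regions: list[tuple[str, int, int]] = field(default_factory=list)
    segregation_models: tuple[str, ...] = (
        "AD-denovo", "AD-inherited", "AR-hom", "AR-comphet", "XL", "MT", "mosaic-candidate",
    )
    segregation_filter: bool = False
    require_index_carrier: bool = True

    def __post_init__(self) -> None:
        for t in (self.af_external_max, self.af_internal_max):
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"frequency threshold out of [0,1]: {t}")
        if self.plp_aggregation not in ("any", "concordant"):
            raise ValueError(f"unknown plp_aggregation {self.plp_aggregation!r}")
        if self.region_restriction not in ("none", "roh", "custom"):
            raise ValueError(f"unknown region_restriction {self.region_restriction!r}")
        active = (
            self.af_external_max < 1.0 or self.af_internal_max < 1.0 or self.require_plp
            or self.consequence_whitelist is not None
            or self.region_restriction != "none" or self.require_index_carrier
        )
        if not active:
            raise ValueError("at least one filter must be active")


@dataclass
class CaseBundle:
    """Everything the filter stack needs for one family: annotated variants,
    pedigree, phenotype, resolved panel and per-case derived context."""

    pedigree: Pedigree
    phenotype: PhenotypeRecord
    variants: list[VariantRecord]
    panel: Optional[GenePanel] = None
    roh_segments: list[inh.RohSegment] = field(default_factory=list)
    froh: float = 0.0
    inferred_consanguineous: bool = False
    cnv_index: inh.CnvIndex = field(default_factory=dict)

    @property
    def case_id(self) -> str:
        return self.pedigree.family_id


# ---------------------------------------------------------------------------
# the filter stack
# ---------------------------------------------------------------------------

def _passes_filters(variant: VariantRecord, bundle: CaseBundle,
                    config: FilterConfig) -> bool:
    """Pure conjunction over the variant's annotations — evaluation order is
    irrelevant to the result."""
    idx_gt = variant.genotypes.get(bundle.pedigree.index_id)
    if config.require_index_carrier:
        if idx_gt is None or idx_gt.is_missing or not idx_gt.carries_alt:
            return False
    if (variant.af_external or 0.0) >= config.af_external_max:
        return False
    if (variant.af_internal or 0.0) >= config.af_internal_max:
        return False
    if bundle.panel is None or variant.gene.upper() not in bundle.panel.genes:
        return False
    if config.require_plp:
        if config.plp_aggregation == "any":
            if not variant.is_plp:
                return False
        elif variant.clinical_significance not in kn.PLP:
            return False
    if config.consequence_whitelist is not None \
            and variant.consequence not in config.consequence_whitelist:
        return False
    if config.region_restriction == "roh":
        if not any(s.contains(variant.contig, variant.pos) for s in bundle.roh_segments):
            return False
    elif config.region_restriction == "custom":
        if not any(c == variant.contig and a <= variant.pos <= b
                   for c, a, b in config.custom_regions):
            return False
    return True


def _fmt_assocs(variant: VariantRecord) -> str:
    return ";".join(
        f"{a.omim_disease_id}:{a.inheritance_mode}:{a.first_association_year or ''}"
        for a in variant.associations
    )


def _fmt_verdicts(verdicts: Sequence[inh.SegregationVerdict]) -> str:
    parts = []
    for v in verdicts:
        parts.append(f"{v.model}=yes" if v.consistent else f"{v.model}=no({v.reason})")
    return ";".join(parts)


def _consanguinity_string(bundle: CaseBundle) -> str:
    reported = bundle.phenotype.reported_consanguinity
    rep = "unknown" if reported is None else ("yes" if reported else "no")
    inf = "yes" if bundle.inferred_consanguineous else "no"
    return f"reported={rep};froh={bundle.froh:.4f};inferred={inf}"


def run_filter_stack(bundle: CaseBundle, kb: kn.KnowledgeBase,
                     config: FilterConfig, *,
                     mosaic_af_bound: float = inh.DEFAULT_MOSAIC_AF_BOUND,
                     allow_reduced_penetrance: bool = False) -> list[CandidateRow]:
    """Apply the filter stack to one case and assemble its candidate rows.

    Variants must already be annotated (:func:`varprio.knowledge.annotate`,
    including the internal cohort frequency). An unresolved/empty panel skips
    the case with a log line, since the preset requires a panel.
    """
    if bundle.panel is None or not bundle.panel.genes:
        logger.warning("case %s: no resolved gene panel — case skipped", bundle.case_id)
        return []

    ped = bundle.pedigree
    survivors = [v for v in bundle.variants if _passes_filters(v, bundle, config)]

    # compound-het pairing among surviving het calls, per gene
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in survivors:
        by_gene.setdefault(v.gene.upper(), []).append(v)
    comphet_partners: dict[tuple, str] = {}
    for gene_variants in by_gene.values():
        for pair in inh.compound_het_pairs(gene_variants, ped):
            comphet_partners[pair.first.key] = f"{pair.second.key_string}({pair.phase})"
            comphet_partners[pair.second.key] = f"{pair.first.key_string}({pair.phase})"

    rows: list[CandidateRow] = []
    for v in survivors:
        verdicts = [
            inh.segregate(v, ped, model, mosaic_af_bound=mosaic_af_bound,
                          allow_reduced_penetrance=allow_reduced_penetrance)
            for model in config.segregation_models
        ]
        if config.segregation_filter and not any(x.consistent for x in verdicts):
            continue
        idx_gt = v.genotypes[ped.index_id]
        rel_gts = ";".join(
            f"{m.experiment_id}={v.genotypes[m.experiment_id].gt_string()}"
            for m in ped.relatives if m.experiment_id in v.genotypes
        )
        in_roh = any(s.contains(v.contig, v.pos) for s in bundle.roh_segments)
        cnv_flag = "clear"
        if idx_gt.is_hom_alt and bundle.cnv_index:
            cnv_flag = inh.cnv_crosscheck(v.contig, v.pos, ped.index_id, bundle.cnv_index)
        seg_str = _fmt_verdicts(verdicts)
        if v.key in comphet_partners:
            seg_str += f";comphet_partner={comphet_partners[v.key]}"
        rows.append(
            CandidateRow(
                case_id=bundle.case_id,
                contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                gene=v.gene, consequence=v.consequence,
                genotype_index=idx_gt.gt_string(),
                genotypes_relatives=rel_gts,
                allelic_fraction=idx_gt.allelic_fraction,
                af_external=v.af_external, af_internal=v.af_internal,
                clinical_significance=v.clinical_significance or "",
                condition=v.condition or "",
                first_plp_year=v.first_plp_year,
                gene_disease_associations=_fmt_assocs(v),
                first_association_year=v.first_association_year,
                pli=v.pli, oe=v.oe,
                acmg_class=v.acmg_class or "",
                acmg_criteria=",".join(v.acmg_criteria),
                hpo_terms=";".join(bundle.phenotype.hpo_terms),
                ordo_codes=";".join(bundle.phenotype.ordo_codes),
                ern=bundle.phenotype.ern_tag,
                consanguinity=_consanguinity_string(bundle),
                segregation=seg_str,
                region_flags=f"roh={'in' if in_roh else 'out'};cnv={cnv_flag}",
                status="candidate",
            )
        )
    rows.sort(key=CandidateRow.sort_key)
    return rows


def flag_het_ar_candidates(rows: Iterable[CandidateRow],
                           kb: kn.KnowledgeBase) -> list[CandidateRow]:
    """Re-status lone heterozygous hits in recessive-only genes.

    A row becomes ``het_AR_candidate`` when the index is heterozygous, every
    gene-disease association of the gene is autosomal recessive, and the case
    has no second surviving variant in that gene (a trans partner would
    complete a compound het; a hom row stands on its own).
    """
    rows = list(rows)
    per_case_gene: dict[tuple[str, str], list[CandidateRow]] = {}
    for row in rows:
        per_case_gene.setdefault((row.case_id, row.gene.upper()), []).append(row)
    for (case_id, gene), group in per_case_gene.items():
        assocs = kb.gene2disease.get(gene, [])
        ar_only = bool(assocs) and all(a.inheritance_mode == "AR" for a in assocs)
        if not ar_only or len(group) != 1:
            continue
        row = group[0]
        if row.genotype_index == "0/1" and row.status == "candidate":
            row.status = "het_AR_candidate"
    return rows


# ---------------------------------------------------------------------------
# case-status registry
# ---------------------------------------------------------------------------

VALID_DECISIONS = ("solved", "under_evaluation", "unsolved")


@dataclass
class CaseRegistry:
    """Event-sourced per-case decision store; the mapping is always exactly
    the replay of the event log."""

    events: list[dict] = field(default_factory=list)

    @property
    def cases(self) -> dict[str, dict]:
        return self.replay(self.events)

    @staticmethod
    def replay(events: Sequence[Mapping]) -> dict[str, dict]:
        state: dict[str, dict] = {}
        for ev in events:
            state[ev["case_id"]] = {
                "status": ev["decision"],
                "solved_variants": list(ev.get("variant_keys") or []),
            }
        return state

    def status_of(self, case_id: str) -> Optional[str]:
        return self.cases.get(case_id, {}).get("status")

    def is_solved(self, case_id: str) -> bool:
        return self.status_of(case_id) == "solved"

    @classmethod
    def load(cls, path: str | Path) -> "CaseRegistry":
        p = Path(path)
        if not p.exists():
            return cls()
        data = json.loads(p.read_text())
        return cls(events=data.get("events", []))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"events": self.events}, indent=1) + "\n")


def tag_case_status(registry: CaseRegistry, case_id: str, decision: str,
                    variant_keys: Sequence[str] | None = None,
                    case_rows: Sequence[CandidateRow] | None = None,
                    ) -> list[CandidateRow]:
    """Record a case-level decision and propagate it to the case's rows.

    Solving requires the causative variant keys to be among the case's rows
    (anything else is fatal); the named rows become ``solved`` and the case's
    other rows ``rejected``.
    """
    if decision not in VALID_DECISIONS:
        raise ValueError(f"unknown decision {decision!r}")
    rows = [r for r in (case_rows or []) if r.case_id == case_id]
    if decision == "solved":
        keys = set(variant_keys or [])
        if not keys:
            raise ValueError("solving a case requires at least one variant key")
        row_keys = {r.variant_key for r in rows}
        unknown = keys - row_keys
        if case_rows is not None and unknown:
            raise ValueError(
                f"case {case_id}: variant keys {sorted(unknown)} are not among its rows")
        for r in rows:
            r.status = "solved" if r.variant_key in keys else "rejected"
    elif decision == "under_evaluation":
        for r in rows:
            if r.status == "candidate":
                r.status = "under_evaluation"
    registry.events.append({
        "seq": len(registry.events),
        "case_id": case_id,
        "decision": decision,
        "variant_keys": sorted(variant_keys) if variant_keys else [],
    })
    return rows


# ---------------------------------------------------------------------------
# knowledge-recency year bins
# ---------------------------------------------------------------------------

def _year_bin(year: Optional[int]) -> str:
    if year is None:
        return "unknown"
    if year >= 2017:
        return ">=2017"
    if year >= 2015:
        return "2015-2016"
    if year >= 2010:
        return "2010-2014"
    return "<2010"


def year_bin_causatives(solved_rows: Sequence[CandidateRow]) -> dict[str, dict[str, float]]:
    """Histogram causative variants by the year their gene (first disease
    association) and the variant itself (first P/LP assertion) entered the
    literature; percentages are over the causative-variant total."""
    total = len(solved_rows)
    out: dict[str, dict[str, float]] = {
        b: {"gene_count": 0, "gene_pct": 0.0, "variant_count": 0, "variant_pct": 0.0}
        for b in YEAR_BINS
    }
    for row in solved_rows:
        out[_year_bin(row.first_association_year)]["gene_count"] += 1
        out[_year_bin(row.first_plp_year)]["variant_count"] += 1
    if total:
        for b in YEAR_BINS:
            out[b]["gene_pct"] = round_half_up(100.0 * out[b]["gene_count"] / total, 1)
            out[b]["variant_pct"] = round_half_up(100.0 * out[b]["variant_count"] / total, 1)
    return out


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    per_ern: dict[str, dict]
    total: dict

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        frame = pd.DataFrame(
            [{"ern": ern, **vals} for ern, vals in sorted(self.per_ern.items())]
            + [{"ern": "TOTAL", **self.total}]
        )
        frame.to_csv(path, sep="\t", index=False)


def _case_status(case_id: str, rows_by_case: Mapping[str, list[CandidateRow]],
                 registry: CaseRegistry) -> str:
    """Case-level tag with precedence solved > under_evaluation > het_AR >
    unsolved."""
    reg = registry.status_of(case_id)
    if reg == "solved":
        return "solved"
    if reg == "under_evaluation":
        return "under_evaluation"
    if any(r.status == "het_AR_candidate" for r in rows_by_case.get(case_id, [])):
        return "het_AR_candidate"
    return "unsolved"


def _summary_block(case_ids: Sequence[str], rows: Sequence[CandidateRow],
                   registry: CaseRegistry,
                   pedigrees: Mapping[str, Pedigree]) -> dict:
    rows_by_case: dict[str, list[CandidateRow]] = {}
    for r in rows:
        rows_by_case.setdefault(r.case_id, []).append(r)
    n_cases = len(case_ids)
    structures = {"trio": 0, "singleton": 0, "other": 0}
    for cid in case_ids:
        structures[pedigrees[cid].structure_class] += 1
    statuses = {s: 0 for s in CASE_STATUSES}
    for cid in case_ids:
        statuses[_case_status(cid, rows_by_case, registry)] += 1
    n_candidate_variants = len(rows)
    n_cases_with = len({r.case_id for r in rows})
    prioritised_rows = [r for r in rows if r.status in ("prioritised", "solved", "under_evaluation")]
    n_prioritised_cases = len({r.case_id for r in prioritised_rows})
    block = {
        "n_cases": n_cases,
        "n_trio": structures["trio"],
        "n_singleton": structures["singleton"],
        "n_other": structures["other"],
        "n_candidate_variants": n_candidate_variants,
        "n_cases_with_candidates": n_cases_with,
        "n_prioritised_variants": len(prioritised_rows),
        "n_prioritised_cases": n_prioritised_cases,
        "n_solved": statuses["solved"],
        "n_under_evaluation": statuses["under_evaluation"],
        "n_het_ar_cases": statuses["het_AR_candidate"],
        "n_unsolved": statuses["unsolved"],
    }
    if n_cases:
        block["pct_trio"] = round_half_up(100.0 * structures["trio"] / n_cases, 1)
        block["pct_singleton"] = round_half_up(100.0 * structures["singleton"] / n_cases, 1)
        block["pct_other"] = round_half_up(100.0 * structures["other"] / n_cases, 1)
        block["pct_cases_with_candidates"] = round_half_up(100.0 * n_cases_with / n_cases, 1)
    if n_cases_with:
        block["mean_candidates_per_case"] = round_half_up(
            n_candidate_variants / n_cases_with, 2)
    return block


def summarize_cohort(rows: Sequence[CandidateRow], registry: CaseRegistry,
                     pedigrees: Sequence[Pedigree],
                     phenotypes: Sequence[PhenotypeRecord]) -> CohortSummary:
    """Per-network and total accounting of the run (cases, family structures,
    candidate/prioritised/solved counts and the derived means/percentages)."""
    ped_by_id = {p.family_id: p for p in pedigrees}
    ern_by_exp = {ph_.experiment_id: ph_.ern_tag for ph_ in phenotypes}
    ern_of_case = {
        p.family_id: ern_by_exp.get(p.index_id, "") for p in pedigrees
    }
    per_ern: dict[str, dict] = {}
    erns = sorted(set(ern_of_case.values()))
    for ern in erns:
        cids = [cid for cid, e in ern_of_case.items() if e == ern]
        ern_rows = [r for r in rows if ern_of_case.get(r.case_id) == ern]
        per_ern[ern] = _summary_block(cids, ern_rows, registry, ped_by_id)
    total = _summary_block(list(ern_of_case), rows, registry, ped_by_id)
    return CohortSummary(per_ern=per_ern, total=total)


def derive_summary_stats(total_cases: int, candidate_variants: int,
                         cases_with_candidates: int, prioritised_variants: int,
                         prioritised_cases: int, solved_cases: int) -> dict[str, float]:
    """The cohort-level derived statistics (means to 2 decimals, percentages
    to 1, half-up) recomputable from the headline counts alone."""
    return {
        "mean_candidates_per_case": round_half_up(
            candidate_variants / cases_with_candidates, 2),
        "mean_prioritised_per_case": round_half_up(
            prioritised_variants / prioritised_cases, 2),
        "pct_cases_with_candidates": round_half_up(
            100.0 * cases_with_candidates / total_cases, 1),
        "pct_prioritised_cases_of_candidate_cases": round_half_up(
            100.0 * prioritised_cases / cases_with_candidates, 1),
        "pct_solved_of_prioritised": round_half_up(
            100.0 * solved_cases / prioritised_cases, 1),
        "pct_solved_of_total": round_half_up(
            100.0 * solved_cases / total_cases, 1),
    }


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and parameters of one reanalysis run (usually loaded from YAML)."""

    vcf_dir: Path
    ped: Path
    phenotypes: Path
    knowledge: dict[str, Path]
    panels_dir: Optional[Path] = None
    ontology: Optional[Path] = None
    hpo_gene_map: Optional[Path] = None
    cnv: Optional[Path] = None
    registry: Optional[Path] = None
    output_dir: Path = Path("varprio-out")
    filters: FilterConfig = field(default_factory=FilterConfig)
    panel_mode: str = "ern"  # "ern" | "on_the_fly" | "explicit"
    panel_path: Optional[Path] = None
    roh_params: inh.RohParams = field(default_factory=inh.RohParams)
    froh_threshold: float = inh.DEFAULT_FROH_THRESHOLD
    mosaic_af_bound: float = inh.DEFAULT_MOSAIC_AF_BOUND
    allow_reduced_penetrance: bool = False
    autosome_length: int = 2_881_000_000  # GRCh37 autosomal span
    include_solved: bool = False
    xlsx_mirror: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; relative paths resolve against the
    config file's directory."""
    base = Path(path).parent
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def resolve(p):
        return None if p is None else (base / p)

    filters = raw.get("filters", {})
    if isinstance(filters.get("consequence_whitelist"), list):
        filters["consequence_whitelist"] = set(filters["consequence_whitelist"])
    if isinstance(filters.get("segregation_models"), list):
        filters["segregation_models"] = tuple(filters["segregation_models"])
    if isinstance(filters.get("custom_regions"), list):
        filters["custom_regions"] = [tuple(r) for r in filters["custom_regions"]]
    inputs = raw.get("inputs", {})
    try:
        cfg = RunConfig(
            vcf_dir=resolve(inputs["vcf_dir"]),
            ped=resolve(inputs["ped"]),
            phenotypes=resolve(inputs["phenotypes"]),
            knowledge={k: resolve(v) for k, v in inputs.get("knowledge", {}).items()},
            panels_dir=resolve(inputs.get("panels_dir")),
            ontology=resolve(inputs.get("ontology")),
            hpo_gene_map=resolve(inputs.get("hpo_gene_map")),
            cnv=resolve(inputs.get("cnv")),
            registry=resolve(raw.get("registry")),
            output_dir=resolve(raw.get("output_dir", "varprio-out")),
            filters=FilterConfig(**filters),
            panel_mode=raw.get("panel", {}).get("mode", "ern"),
            panel_path=resolve(raw.get("panel", {}).get("path")),
            roh_params=inh.RohParams(**raw.get("roh", {})),
            froh_threshold=raw.get("froh", {}).get("threshold", inh.DEFAULT_FROH_THRESHOLD),
            mosaic_af_bound=raw.get("mosaic", {}).get("af_bound", inh.DEFAULT_MOSAIC_AF_BOUND),
            allow_reduced_penetrance=raw.get("allow_reduced_penetrance", False),
            autosome_length=raw.get("autosome_length", 2_881_000_000),
            include_solved=raw.get("include_solved", False),
            xlsx_mirror=raw.get("xlsx_mirror", False),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid run configuration {path}: {exc}") from exc
    if cfg.panel_mode not in ("ern", "on_the_fly", "explicit"):
        raise ValueError(f"unknown panel mode {cfg.panel_mode!r}")
    return cfg


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    rows: list[CandidateRow]
    summary: CohortSummary
    manifest: dict
    n_processed: int
    n_failed: int


#: population-AF band of markers informative for autozygosity. A site where
#: nearly everyone is homozygous-reference says nothing about ROH, so only
#: polymorphic sites delimit homozygous runs.
ROH_INFORMATIVE_AF = (0.05, 0.95)


def _diploid_autosomal_sites(variants: Sequence[VariantRecord],
                             index_id: str) -> list[inh.GenotypeSite]:
    lo, hi = ROH_INFORMATIVE_AF
    sites = []
    for v in variants:
        if v.contig in ("X", "Y", "MT"):
            continue
        if v.af_external is None or not (lo <= v.af_external <= hi):
            continue
        gt = v.genotypes.get(index_id)
        if gt is None or gt.is_missing or gt.ploidy != 2:
            continue
        sites.append((v.contig, v.pos, gt.allele_count))
    return sites


def reanalyse_cohort(config: RunConfig,
                     case_selection: Optional[Sequence[str]] = None) -> RunResult:
    """Run the full per-case sequential reanalysis.

    Cases are processed one by one; a failure in one case (unreadable VCF,
    missing index sample, ...) is isolated and logged, it does not abort the
    cohort. Output (candidate table, summary, manifest) is deterministic for
    fixed inputs and configuration.
    """
    t0 = time.time()
    pedigrees = read_ped(config.ped)
    phenotypes = read_phenotype_records(config.phenotypes)
    pheno_by_exp = {p.experiment_id: p for p in phenotypes}
    kb = kn.load_knowledge(config.knowledge)
    registry = CaseRegistry.load(config.registry) if config.registry else CaseRegistry()

    panels: dict[str, GenePanel] = {}
    if config.panel_mode == "ern" and config.panels_dir:
        for f in sorted(Path(config.panels_dir).glob("*.tsv")):
            panels[f.stem] = read_gene_panel(f)
    explicit_panel = read_gene_panel(config.panel_path) if config.panel_path else None
    ontology = ph.Ontology.from_obo(config.ontology) if config.ontology else None
    hpo_map = ph.load_hpo_gene_map(config.hpo_gene_map) if config.hpo_gene_map else {}
    cnv_index = inh.build_cnv_index(read_cnv_bed(config.cnv)) if config.cnv else {}

    selected = [p for p in pedigrees
                if case_selection is None or p.family_id in case_selection]
    if not config.include_solved:
        skipped_solved = [p.family_id for p in selected if registry.is_solved(p.family_id)]
        selected = [p for p in selected if not registry.is_solved(p.family_id)]
    else:
        skipped_solved = []

    # pass 1: load all family VCFs and pool index genotypes for the internal AF
    family_variants: dict[str, list[VariantRecord]] = {}
    failures: dict[str, str] = {}
    index_gts: dict[kn.VariantKey, list] = {}
    for ped in selected:
        vcf_path = Path(config.vcf_dir) / f"{ped.family_id}.vcf"
        try:
            variants = read_vcf(vcf_path, ped)
        except Exception as exc:
            logger.error("case %s failed to load: %s", ped.family_id, exc)
            failures[ped.family_id] = str(exc)
            continue
        family_variants[ped.family_id] = variants
        for v in variants:
            gt = v.genotypes.get(ped.index_id)
            if gt is not None:
                index_gts.setdefault(v.key, []).append(gt)
    internal_af = kn.cohort_internal_frequencies(index_gts)

    # pass 2: per-case annotation + filter stack, sequentially
    all_rows: list[CandidateRow] = []
    per_case_manifest: list[dict] = []
    for ped in selected:
        if ped.family_id in failures:
            per_case_manifest.append(
                {"case_id": ped.family_id, "status": "failed",
                 "error": failures[ped.family_id]})
            continue
        try:
            variants = family_variants[ped.family_id]
            for v in variants:
                kn.annotate(v, kb, af_internal=internal_af.get(v.key, 0.0))
            pheno = pheno_by_exp.get(
                ped.index_id, PhenotypeRecord(experiment_id=ped.index_id))
            if config.panel_mode == "explicit":
                panel = explicit_panel
            elif config.panel_mode == "on_the_fly":
                if ontology is None:
                    raise ValueError("on-the-fly panels need an ontology and HPO-gene map")
                panel = ph.on_the_fly_panel(pheno, hpo_map, ontology)
            else:
                panel = panels.get(pheno.ern_tag)
            roh = inh.detect_roh(ped.index_id,
                                 _diploid_autosomal_sites(variants, ped.index_id),
                                 config.roh_params)
            froh, consang = inh.infer_consanguinity(
                roh, config.autosome_length, config.froh_threshold)
            bundle = CaseBundle(
                pedigree=ped, phenotype=pheno, variants=variants, panel=panel,
                roh_segments=roh, froh=froh, inferred_consanguineous=consang,
                cnv_index=cnv_index,
            )
            rows = run_filter_stack(
                bundle, kb, config.filters,
                mosaic_af_bound=config.mosaic_af_bound,
                allow_reduced_penetrance=config.allow_reduced_penetrance)
            all_rows.extend(rows)
            per_case_manifest.append(
                {"case_id": ped.family_id, "status": "ok",
                 "n_variants": len(variants), "n_candidates": len(rows),
                 "froh": round(froh, 4)})
            logger.info("case %s: %d variants -> %d candidates",
                        ped.family_id, len(variants), len(rows))
        except Exception as exc:
            logger.error("case %s failed: %s", ped.family_id, exc)
            failures[ped.family_id] = str(exc)
            per_case_manifest.append(
                {"case_id": ped.family_id, "status": "failed", "error": str(exc)})

    all_rows = flag_het_ar_candidates(all_rows, kb)
    all_rows.sort(key=CandidateRow.sort_key)

    processed = [p for p in selected if p.family_id not in failures]
    summary = summarize_cohort(all_rows, registry, processed, phenotypes)
    manifest = {
        "config_hash": _config_hash(config),
        "inputs": {
            "vcf_dir": str(config.vcf_dir), "ped": str(config.ped),
            "phenotypes": str(config.phenotypes),
            "knowledge": {k: str(v) for k, v in config.knowledge.items()},
            "registry": str(config.registry) if config.registry else None,
        },
        "knowledge_versions": kb.versions,
        "started": t0,
        "finished": time.time(),
        "skipped_solved": skipped_solved,
        "cases": per_case_manifest,
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_candidate_table(
        all_rows, out / "candidates.tsv",
        header_comments=kb.version_stamps(),
        xlsx_path=(out / "candidates.xlsx") if config.xlsx_mirror else None)
    summary.to_tsv(out / "summary.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")

    return RunResult(rows=all_rows, summary=summary, manifest=manifest,
                     n_processed=len(processed), n_failed=len(failures))
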