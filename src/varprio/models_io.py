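"""Domain types and readers/writers for the external formats the engine touches.

The engine consumes pre-annotated per-family VCFs (GRCh37 convention, one gene
symbol and consequence term per record in INFO/GENE and INFO/CSQ), 6-column PED
pedigrees, phenopacket-style JSON phenotype records, BED CNV calls and TSV
knowledge tables, and it emits a fixed-width TSV candidate table (with an
optional XLSX mirror for distribution).

Coordinate convention: 1-based, inclusive, VCF-style everywhere. BED intervals
are converted on read. Chromosome names are normalized by stripping any "chr"
prefix; the mitochondrial contig is normalized to "MT". Multi-allelic sites are
decomposed into one record per alternate allele on read; indel normalization
(left-alignment) is assumed to have been done by the upstream pipeline.

A missing genotype (./.) is "unknown", never homozygous-reference: unknown
calls are excluded from allele-frequency denominators and cannot confirm a
de novo event during segregation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

logger = logging.getLogger("varprio")

HPO_PATTERN = re.compile(r"^HP:\d{7}$")

#: canonical contig sort order (GRCh37 naming, no "chr" prefix)
_CONTIGS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
_CONTIG_RANK = {c: i for i, c in enumerate(_CONTIGS)}


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed or does not cover the index case."""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (e.g. cyclic parentage)."""


def normalize_contig(contig: str) -> str:
    c = contig[3:] if contig.lower().startswith("chr") else contig
    if c in ("M", "m", "mt"):
        return "MT"
    return c.upper() if c.lower() in ("x", "y") else c


def contig_sort_key(contig: str) -> tuple[int, str]:
    return (_CONTIG_RANK.get(contig, len(_CONTIG_RANK)), contig)


# ---------------------------------------------------------------------------
# genotypes and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one decomposed (single-alt) site.

    ``allele_count`` counts copies of *this* alternate allele: 0/1/2 on
    diploid calls, 0/1 on haploid calls (hemizygous male X, mtDNA). ``None``
    means the call is missing/unknown.
    """

    allele_count: Optional[int]
    ploidy: int = 2
    allelic_fraction: Optional[float] = None

    @property
    def is_missing(self) -> bool:
        return self.allele_count is None

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.allele_count == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.allele_count is not None and self.allele_count == self.ploidy

    @property
    def is_hom_ref(self) -> bool:
        return self.allele_count == 0

    @property
    def carries_alt(self) -> bool:
        return self.allele_count is not None and self.allele_count >= 1

    def gt_string(self) -> str:
        if self.allele_count is None:
            return "." if self.ploidy == 1 else "./."
        if self.ploidy == 1:
            return str(self.allele_count)
        return {0: "0/0", 1: "0/1", 2: "1/1"}[self.allele_count]


@dataclass
class VariantRecord:
    """One normalized alternate allele at a genomic position.

    Knowledge fields (frequencies, assertions, associations, constraint, ACMG)
    start out ``None``/empty and are populated by :func:`varprio.knowledge.annotate`.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    quality_flags: str = "PASS"

    # knowledge annotations (joined later; see varprio.knowledge)
    af_external: Optional[float] = None
    af_internal: Optional[float] = None
    clinical_significance: Optional[str] = None
    condition: Optional[str] = None
    first_plp_year: Optional[int] = None
    is_plp: bool = False
    associations: tuple = ()
    first_association_year: Optional[int] = None
    pli: Optional[float] = None
    oe: Optional[float] = None
    acmg_class: Optional[str] = None
    acmg_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        if not self.gene and not self.consequence:
            self.consequence = "intergenic_variant"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def key_string(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    def sort_key(self):
        return (*contig_sort_key(self.contig), self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedMember:
    experiment_id: str
    sex: str  # "male" | "female" | "unknown"
    affected: Optional[bool]  # None = unknown status
    father_id: Optional[str] = None
    mother_id: Optional[str] = None


@dataclass
class Pedigree:
    family_id: str
    members: list[PedMember]
    index_id: str

    @property
    def index(self) -> PedMember:
        return next(m for m in self.members if m.experiment_id == self.index_id)

    def member(self, experiment_id: str) -> Optional[PedMember]:
        return next((m for m in self.members if m.experiment_id == experiment_id), None)

    @property
    def father(self) -> Optional[PedMember]:
        fid = self.index.father_id
        return self.member(fid) if fid else None

    @property
    def mother(self) -> Optional[PedMember]:
        mid = self.index.mother_id
        return self.member(mid) if mid else None

    @property
    def relatives(self) -> list[PedMember]:
        return [m for m in self.members if m.experiment_id != self.index_id]

    @property
    def structure_class(self) -> str:
        """trio iff index plus both parents and nobody else; singleton iff index only."""
        if len(self.members) == 1:
            return "singleton"
        ids = {m.experiment_id for m in self.members}
        idx = self.index
        if (
            len(self.members) == 3
            and idx.father_id in ids
            and idx.mother_id in ids
        ):
            return "trio"
        return "other"


_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_PHENO_CODES = {"2": True, "1": False, "0": None, "-9": None}


def _pick_index(members: list[PedMember], family_id: str) -> str:
    """The index case is the affected member who is not a parent of another
    member; ties broken by experiment id. Falls back (with a warning) to the
    first member when nobody is flagged affected."""
    parent_ids = {m.father_id for m in members} | {m.mother_id for m in members}
    affected = [m for m in members if m.affected]
    pool = affected or members
    if not affected:
        logger.warning("family %s has no affected member; using %s as index",
                       family_id, members[0].experiment_id)
    non_parents = [m for m in pool if m.experiment_id not in parent_ids]
    chosen = sorted(non_parents or pool, key=lambda m: m.experiment_id)[0]
    return chosen.experiment_id


def _check_acyclic(members: list[PedMember], family_id: str) -> None:
    parents = {m.experiment_id: [p for p in (m.father_id, m.mother_id) if p] for m in members}
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        state[node] = 1
        for p in parents.get(node, []):
            s = state.get(p)
            if s == 1:
                raise PedigreeError(f"cyclic parentage in family {family_id} at {node}")
            if s is None:
                visit(p)
        state[node] = 2

    for m in members:
        if state.get(m.experiment_id) is None:
            visit(m.experiment_id)


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

    ``0`` parent ids mean "absent"; unknown sex codes are warned about and
    mapped to "unknown". Cyclic parentage is fatal.
    """
    rows_by_family: dict[str, list[PedMember]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 PED columns, got {len(parts)}")
        fam, iid, fid, mid, sex, pheno = parts[:6]
        if sex not in _SEX_CODES:
            logger.warning("%s:%d: unknown sex code %r; using unknown", path, lineno, sex)
        member = PedMember(
            experiment_id=iid,
            sex=_SEX_CODES.get(sex, "unknown"),
            affected=_PHENO_CODES.get(pheno, None),
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
        )
        rows_by_family.setdefault(fam, []).append(member)

    pedigrees = []
    for fam, members in rows_by_family.items():
        _check_acyclic(members, fam)
        pedigrees.append(Pedigree(fam, members, _pick_index(members, fam)))
    return pedigrees


# ---------------------------------------------------------------------------
# phenotype records
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeRecord:
    experiment_id: str
    hpo_terms: list[str] = field(default_factory=list)
    ordo_codes: list[str] = field(default_factory=list)
    omim_codes: list[str] = field(default_factory=list)
    ern_tag: str = ""
    reported_consanguinity: Optional[bool] = None


def read_phenotype_records(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenopacket-style JSON array of per-experiment phenotype records.

    Each record carries a subject id, phenotypicFeatures with HPO term ids,
    diseases with ORDO/OMIM term ids, and (as top-level extensions) the
    submitting network tag and reported consanguinity. Records without a
    subject id are skipped with a log line; malformed HPO ids are dropped.
    """
    data = json.loads(Path(path).read_text())
    records: list[PhenotypeRecord] = []
    for i, rec in enumerate(data):
        exp_id = rec.get("subject", {}).get("id") or rec.get("id")
        if not exp_id:
            logger.warning("%s: record %d has no experiment id; skipped", path, i)
            continue
        hpos = []
        for feat in rec.get("phenotypicFeatures", []):
            term = feat.get("type", {}).get("id", "")
            if HPO_PATTERN.match(term):
                hpos.append(term)
            else:
                logger.warning("%s: %s: dropping malformed HPO id %r", path, exp_id, term)
        ordo, omim = [], []
        for dis in rec.get("diseases", []):
            term = dis.get("term", {}).get("id", "")
            if term.startswith(("ORPHA:", "Orphanet:")):
                ordo.append(term)
            elif term.startswith("OMIM:"):
                omim.append(term)
        records.append(
            PhenotypeRecord(
                experiment_id=exp_id,
                hpo_terms=hpos,
                ordo_codes=ordo,
                omim_codes=omim,
                ern_tag=rec.get("ern", ""),
                reported_consanguinity=rec.get("consanguinity"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# gene panels and CNV calls
# ---------------------------------------------------------------------------

@dataclass
class GenePanel:
    panel_id: str
    source: str  # "ERN-curated" | "external" | "on-the-fly"
    genes: set[str]
    ranked: list[str] = field(default_factory=list)  # only for ranked on-the-fly panels

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes if g}

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def read_gene_panel(path: str | Path, panel_id: str | None = None,
                    source: str = "ERN-curated") -> GenePanel:
    """Read a one-gene-per-line (or TSV first-column) panel file."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("gene"):
            continue
        genes.add(line.split("\t")[0].strip().upper())
    if not genes:
        raise ValueError(f"gene panel {path} is empty")
    return GenePanel(panel_id or Path(path).stem, source, genes)


@dataclass(frozen=True)
class CnvCall:
    experiment_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    copy_state: str  # "deletion-het" | "deletion-hom" | "duplication"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CNV start > end: {self}")


def read_cnv_bed(path: str | Path) -> list[CnvCall]:
    """Read CNV calls from BED (chrom, start, end, experiment_id, copy_state);
    half-open 0-based BED coordinates are converted to 1-based inclusive."""
    calls = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: need 5 BED columns (chrom,start,end,experiment,copy_state)")
        chrom, start, end, exp_id, state = parts[:5]
        calls.append(CnvCall(exp_id, normalize_contig(chrom), int(start) + 1, int(end), state))
    return calls


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _genotype_from_entry(entry: Sequence, alt_index: int,
                         ad_row=None) -> GenotypeCall:
    """Decode one cyvcf2 genotype entry ([a1, a2, phased] or [a, phased]) for
    the alt allele with 1-based ALT-column index ``alt_index``."""
    alleles = [a for a in entry[:-1]]
    ploidy = len(alleles)
    if any(a < 0 for a in alleles):
        return GenotypeCall(None, ploidy)
    count = sum(1 for a in alleles if a == alt_index)
    af = None
    if ad_row is not None and len(ad_row) > alt_index:
        depths = [int(d) for d in ad_row if int(d) >= 0]
        alt_depth = int(ad_row[alt_index])
        total = sum(depths)
        if alt_depth >= 0 and total > 0:
            af = alt_depth / total
    return GenotypeCall(count, ploidy, af)


def read_vcf(path: str | Path, pedigree: Pedigree) -> list[VariantRecord]:
    """Read a per-family VCF into decomposed, sorted :class:`VariantRecord` s.

    Sample columns are matched to pedigree members by experiment id; members
    absent from the VCF are tolerated (logged), a missing index case is fatal.
    """
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # htslib raises plain OSError on bad files
        raise VcfParseError(f"failed to parse VCF {path}: {exc}") from exc

    if pedigree.index_id not in samples:
        raise VcfParseError(
            f"index case {pedigree.index_id} of family {pedigree.family_id} "
            f"is not a sample of {path}"
        )
    member_ids = [m.experiment_id for m in pedigree.members]
    for mid in member_ids:
        if mid not in samples:
            logger.warning("family %s member %s missing from %s", pedigree.family_id, mid, path)
    wanted = [(i, s) for i, s in enumerate(samples) if s in member_ids]

    records: list[VariantRecord] = []
    try:
        for v in vcf:
            ad = v.format("AD")
            gts = v.genotypes
            for k, alt in enumerate(v.ALT):
                genotypes = {
                    s: _genotype_from_entry(gts[i], k + 1, None if ad is None else ad[i])
                    for i, s in enumerate(samples) if s in member_ids
                }
                records.append(
                    VariantRecord(
                        contig=normalize_contig(v.CHROM),
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        gene=(v.INFO.get("GENE") or ""),
                        consequence=(v.INFO.get("CSQ") or ""),
                        genotypes=genotypes,
                        quality_flags=v.FILTER or "PASS",
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"failed while reading {path}: {exc}") from exc

    records.sort(key=VariantRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# candidate table
# ---------------------------------------------------------------------------

#: fixed column contract of the candidate table (28 columns)
CANDIDATE_TABLE_COLUMNS = [
    "case_id", "contig", "pos", "ref", "alt", "gene", "consequence",
    "genotype_index", "genotypes_relatives", "allelic_fraction",
    "af_external", "af_internal", "clinical_significance", "condition",
    "first_plp_year", "gene_disease_associations", "first_association_year",
    "pli", "oe", "acmg_class", "acmg_criteria", "hpo_terms", "ordo_codes",
    "ern", "consanguinity", "segregation", "region_flags", "status",
]

_INT_COLUMNS = {"pos", "first_plp_year", "first_association_year"}
_FLOAT_COLUMNS = {"allelic_fraction", "af_external", "af_internal", "pli", "oe"}


@dataclass
class CandidateRow:
    """One variant x one index case surviving the filter stack.

    String-typed summary fields (associations, segregation verdicts,
    consanguinity, region flags) use ``;``-joined ``key=value`` micro-syntax
    so the table round-trips losslessly through TSV.
    """

    case_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    genotype_index: str = ""
    genotypes_relatives: str = ""
    allelic_fraction: Optional[float] = None
    af_external: Optional[float] = None
    af_internal: Optional[float] = None
    clinical_significance: str = ""
    condition: str = ""
    first_plp_year: Optional[int] = None
    gene_disease_associations: str = ""
    first_association_year: Optional[int] = None
    pli: Optional[float] = None
    oe: Optional[float] = None
    acmg_class: str = ""
    acmg_criteria: str = ""
    hpo_terms: str = ""
    ordo_codes: str = ""
    ern: str = ""
    consanguinity: str = ""
    segregation: str = ""
    region_flags: str = ""
    status: str = "candidate"

    @property
    def variant_key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    def sort_key(self):
        return (self.case_id, *contig_sort_key(self.contig), self.pos, self.ref, self.alt)


VALID_ROW_STATUSES = {
    "candidate", "prioritised", "solved", "under_evaluation",
    "het_AR_candidate", "rejected",
}


def _format_cell(value) -> str:
    if value is None or value == "":
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_candidate_table(rows: Iterable[CandidateRow], path: str | Path,
                          header_comments: Sequence[str] = (),
                          xlsx_path: str | Path | None = None) -> None:
    """Write the candidate table as TSV (deterministic order: case id, then
    variant key). ``header_comments`` become ``#``-prefixed lines before the
    header — used for knowledge-table version stamps. Optionally mirrors the
    table to XLSX for distribution."""
    ordered = sorted(rows, key=CandidateRow.sort_key)
    for row in ordered:
        if row.status not in VALID_ROW_STATUSES:
            raise ValueError(f"invalid row status {row.status!r}")
    lines = [f"# {c}" for c in header_comments]
    lines.append("\t".join(CANDIDATE_TABLE_COLUMNS))
    for row in ordered:
        lines.append("\t".join(_format_cell(getattr(row, c)) for c in CANDIDATE_TABLE_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")

    if xlsx_path is not None:
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "candidates"
        ws.append(CANDIDATE_TABLE_COLUMNS)
        for row in ordered:
            ws.append([getattr(row, c) for c in CANDIDATE_TABLE_COLUMNS])
        wb.save(str(xlsx_path))


def read_candidate_table(path: str | Path) -> list[CandidateRow]:
    """Re-parse a TSV candidate table written by :func:`write_candidate_table`."""
    lines = [l for l in Path(path).read_text().splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    if header != CANDIDATE_TABLE_COLUMNS:
        raise ValueError(f"unexpected candidate-table header in {path}")
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        kwargs = {}
        for col, cell in zip(header, cells):
            if cell == "":
                kwargs[col] = None if col in _INT_COLUMNS | _FLOAT_COLUMNS else ""
            elif col in _INT_COLUMNS:
                kwargs[col] = int(cell)
            elif col in _FLOAT_COLUMNS:
                kwargs[col] = float(cell)
            else:
                kwargs[col] = cell
        rows.append(CandidateRow(**kwargs))
    return rows
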