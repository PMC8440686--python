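"""Inheritance-aware analyses: segregation verdicts per inheritance model,
compound-heterozygote pairing by parental origin, run-of-homozygosity (ROH)
detection from exome genotypes, FROH-based consanguinity inference, and the
cross-check of homozygous candidate calls against heterozygous-deletion CNVs.

Segregation *annotates* candidates, it does not filter them: human reviewers
see inconsistent rows too. Rules operate on whatever relatives carry called
genotypes; a family with no informative relatives (singleton, or everyone
uncalled at the site) is unconstrained and every model returns consistent.
A missing genotype is unknown, never homozygous-reference — in particular an
uncalled parent can never confirm a de novo event.

ROH detection is tuned for sparse exome sites: a run must span at least
``min_length_bp`` (default 1 Mb), contain at least ``min_sites`` called sites
and tolerates at most ``max_het`` heterozygous calls. Runs are found by a
leftmost-greedy scan, so the reported segments are non-overlapping and each is
maximal (it can be extended in neither direction without exceeding the het
budget). FROH is the fraction of the autosome covered by ROH segments;
parental relatedness closer than second cousins corresponds to roughly
FROH >= 0.03, the default consanguinity threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .models_io import CnvCall, GenotypeCall, Pedigree, PedMember, VariantRecord

logger = logging.getLogger("varprio")

SEGREGATION_MODELS = (
    "AD-denovo", "AD-inherited", "AR-hom", "AR-comphet", "XL", "MT", "mosaic-candidate",
)

DEFAULT_MOSAIC_AF_BOUND = 0.30
DEFAULT_FROH_THRESHOLD = 0.03


@dataclass(frozen=True)
class SegregationVerdict:
    model: str
    consistent: bool
    reason: str = ""

    def __post_init__(self):
        if not self.consistent and not self.reason:
            raise ValueError("an inconsistent verdict needs a reason")


def _called(gt: Optional[GenotypeCall]) -> bool:
    return gt is not None and not gt.is_missing


def _genotype_of(variant: VariantRecord, member: Optional[PedMember]) -> Optional[GenotypeCall]:
    if member is None:
        return None
    return variant.genotypes.get(member.experiment_id)


def segregate(variant: VariantRecord, pedigree: Pedigree, model: str, *,
              mosaic_af_bound: float = DEFAULT_MOSAIC_AF_BOUND,
              allow_reduced_penetrance: bool = False) -> SegregationVerdict:
    """Judge consistency of one variant's family genotypes with one model."""
    if model not in SEGREGATION_MODELS:
        raise ValueError(f"unknown segregation model {model!r}")

    index = pedigree.index
    idx_gt = variant.genotypes.get(pedigree.index_id)
    if not _called(idx_gt):
        return SegregationVerdict(model, False, "index uncalled")

    relatives = [(m, variant.genotypes.get(m.experiment_id)) for m in pedigree.relatives]
    called_relatives = [(m, gt) for m, gt in relatives if _called(gt)]
    if not called_relatives:
        return SegregationVerdict(model, True, "no relatives — unconstrained")

    father_gt = _genotype_of(variant, pedigree.father)
    mother_gt = _genotype_of(variant, pedigree.mother)

    if model == "AD-denovo":
        if not idx_gt.is_het:
            return SegregationVerdict(model, False, "index not heterozygous")
        for label, gt in (("father", father_gt), ("mother", mother_gt)):
            if not _called(gt):
                return SegregationVerdict(
                    model, False, f"{label} uncalled — cannot confirm de novo")
            if gt.carries_alt:
                return SegregationVerdict(model, False, f"{label} carries the allele")
        return SegregationVerdict(model, True, "de novo in index")

    if model == "AD-inherited":
        if not idx_gt.is_het:
            return SegregationVerdict(model, False, "index not heterozygous")
        affected_carrier = False
        for m, gt in called_relatives:
            if m.affected and gt.carries_alt:
                affected_carrier = True
            if m.affected is False and gt.carries_alt and not allow_reduced_penetrance:
                return SegregationVerdict(
                    model, False, f"unaffected relative {m.experiment_id} carries the allele")
        if not affected_carrier:
            return SegregationVerdict(model, False, "no affected relative carries the allele")
        return SegregationVerdict(model, True, "co-segregates with affected relatives")

    if model == "AR-hom":
        if not idx_gt.is_hom_alt:
            return SegregationVerdict(model, False, "index not homozygous for the allele")
        for label, gt in (("father", father_gt), ("mother", mother_gt)):
            if _called(gt) and not gt.carries_alt:
                return SegregationVerdict(model, False, f"{label} carries no allele copy")
        for m, gt in called_relatives:
            if m.affected is False and gt.is_hom_alt:
                return SegregationVerdict(
                    model, False, f"unaffected relative {m.experiment_id} homozygous")
        return SegregationVerdict(model, True, "homozygous in index, parents carriers")

    if model == "AR-comphet":
        if not idx_gt.is_het:
            return SegregationVerdict(model, False, "index not heterozygous")
        if _called(father_gt) and _called(mother_gt):
            if father_gt.carries_alt == mother_gt.carries_alt:
                return SegregationVerdict(
                    model, False, "allele not attributable to exactly one parent")
        return SegregationVerdict(model, True, "heterozygous in index — pairable")

    if model == "XL":
        if variant.contig != "X":
            return SegregationVerdict(model, False, "variant not on chromosome X")
        for m, gt in called_relatives:
            if m.affected is False and m.sex == "male" and gt.carries_alt \
                    and not allow_reduced_penetrance:
                return SegregationVerdict(
                    model, False, f"unaffected male relative {m.experiment_id} carries the allele")
        if index.sex == "male":
            if not idx_gt.carries_alt:
                return SegregationVerdict(model, False, "male index carries no allele copy")
            return SegregationVerdict(model, True, "hemizygous in male index")
        if not idx_gt.is_hom_alt:
            return SegregationVerdict(model, False, "female index not homozygous")
        return SegregationVerdict(model, True, "homozygous in female index")

    if model == "MT":
        if variant.contig != "MT":
            return SegregationVerdict(model, False, "variant not mitochondrial")
        if not idx_gt.carries_alt:
            return SegregationVerdict(model, False, "index carries no allele copy")
        return SegregationVerdict(model, True, "mitochondrial variant in index")

    # mosaic-candidate: a reporting flag, never a filter
    if not idx_gt.carries_alt:
        return SegregationVerdict(model, False, "index carries no allele copy")
    if idx_gt.allelic_fraction is None:
        return SegregationVerdict(model, False, "no allelic fraction available")
    if idx_gt.allelic_fraction >= mosaic_af_bound:
        return SegregationVerdict(
            model, False,
            f"allelic fraction {idx_gt.allelic_fraction:.2f} >= {mosaic_af_bound:.2f}")
    return SegregationVerdict(model, True, "low allelic fraction — possible mosaicism")


# ---------------------------------------------------------------------------
# compound heterozygotes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompHetPair:
    first: VariantRecord
    second: VariantRecord
    phase: str  # "trans" | "unknown"


def _parental_origin(variant: VariantRecord, pedigree: Pedigree) -> Optional[str]:
    """"paternal" / "maternal" when the allele is attributable to exactly one
    called parent, else None (ambiguous, de novo, or parent uncalled)."""
    father_gt = _genotype_of(variant, pedigree.father)
    mother_gt = _genotype_of(variant, pedigree.mother)
    if not (_called(father_gt) and _called(mother_gt)):
        return None
    pat, mat = father_gt.carries_alt, mother_gt.carries_alt
    if pat and not mat:
        return "paternal"
    if mat and not pat:
        return "maternal"
    return None


def compound_het_pairs(variants_in_gene: Sequence[VariantRecord],
                       pedigree: Pedigree) -> list[CompHetPair]:
    """Pair heterozygous index variants of one gene into potential compound
    heterozygotes.

    With both parents genotyped, only trans pairs are returned (one variant
    paternal-only, the other maternal-only). Without both parents every
    unordered het pair is returned, flagged phase-unknown.
    """
    hets = [v for v in variants_in_gene
            if _called(v.genotypes.get(pedigree.index_id))
            and v.genotypes[pedigree.index_id].is_het]
    if len(hets) < 2:
        return []
    hets.sort(key=VariantRecord.sort_key)

    both_parents = (
        pedigree.father is not None
        and pedigree.mother is not None
        and all(
            _called(v.genotypes.get(pedigree.father.experiment_id))
            and _called(v.genotypes.get(pedigree.mother.experiment_id))
            for v in hets
        )
    )

    pairs: list[CompHetPair] = []
    if both_parents:
        for a, b in itertools.combinations(hets, 2):
            origins = {_parental_origin(a, pedigree), _parental_origin(b, pedigree)}
            if origins == {"paternal", "maternal"}:
                pairs.append(CompHetPair(a, b, "trans"))
    else:
        for a, b in itertools.combinations(hets, 2):
            pairs.append(CompHetPair(a, b, "unknown"))
    return pairs


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RohParams:
    min_length_bp: int = 1_000_000
    min_sites: int = 25
    max_het: int = 1


@dataclass(frozen=True)
class RohSegment:
    experiment_id: str
    contig: str
    start: int
    end: int
    n_sites: int
    n_het_used: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos <= self.end


GenotypeSite = tuple[str, int, int]  # (contig, pos, allele_count 0/1/2)


def detect_roh(experiment_id: str, sites: Sequence[GenotypeSite],
               params: RohParams = RohParams()) -> list[RohSegment]:
    """Find maximal homozygous runs over called genotype sites.

    ``sites`` are (contig, pos, allele_count) triples for *called* diploid
    sites, sorted by position within each contig (unsorted input is fatal).
    A het call is allele_count == 1. The greedy scan starts each run at the
    first unconsumed homozygous site and extends it as far right as the het
    budget allows; boundaries are trimmed to homozygous sites. Two qualifying
    runs separated by more than ``max_het`` het calls therefore never merge.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, pos, count in sites:
        by_contig.setdefault(contig, []).append((pos, count))
    segments: list[RohSegment] = []
    for contig, items in by_contig.items():
        positions = [p for p, _ in items]
        if positions != sorted(positions):
            raise ValueError(f"genotype sites on {contig} are not position-sorted")
        het = [c == 1 for _, c in items]
        n = len(items)
        i = 0
        while i < n:
            if het[i]:
                i += 1
                continue
            hets_used = 0
            last_hom = i
            k = i + 1
            while k < n:
                if het[k]:
                    if hets_used + 1 > params.max_het:
                        break
                    hets_used += 1
                else:
                    last_hom = k
                k += 1
            j = last_hom
            n_sites = j - i + 1
            start, end = positions[i], positions[j]
            hets_inside = sum(het[i:j + 1])
            if n_sites >= params.min_sites and (end - start + 1) >= params.min_length_bp:
                segments.append(RohSegment(experiment_id, contig, start, end,
                                           n_sites, hets_inside))
            i = j + 1
    segments.sort(key=lambda s: (s.contig, s.start))
    return segments


def infer_consanguinity(roh_segments: Iterable[RohSegment], autosome_length: int,
                        threshold: float = DEFAULT_FROH_THRESHOLD) -> tuple[float, bool]:
    """FROH = summed autosomal ROH length / autosome length; consanguineous
    when FROH reaches the threshold (default 0.03, about second-cousin
    parental relatedness or closer)."""
    if autosome_length <= 0:
        raise ValueError("autosome_length must be positive")
    total = sum(s.length_bp for s in roh_segments)
    froh = min(total / autosome_length, 1.0)
    return froh, froh >= threshold


# ---------------------------------------------------------------------------
# CNV cross-check
# ---------------------------------------------------------------------------

CnvIndex = dict[tuple[str, str], IntervalTree]


def build_cnv_index(cnv_calls: Iterable[CnvCall]) -> CnvIndex:
    """Index heterozygous-deletion calls by (experiment, contig) for overlap
    queries."""
    index: CnvIndex = {}
    for call in cnv_calls:
        if call.copy_state != "deletion-het":
            continue
        tree = index.setdefault((call.experiment_id, call.contig), IntervalTree())
        tree.addi(call.start, call.end + 1, call.copy_state)  # half-open tree interval
    return index


def cnv_crosscheck(contig: str, pos: int, experiment_id: str,
                   cnv_index: CnvIndex) -> str:
    """"suspect" when a heterozygous deletion of the experiment overlaps the
    position (a hom call there may be a hemizygous artefact), else "clear"."""
    tree = cnv_index.get((experiment_id, contig))
    if tree is not None and tree.overlaps_point(pos):
        return "suspect"
    return "clear"
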