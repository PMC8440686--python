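"""Segregation truth tables, compound-het pairing, ROH detection, FROH-based
consanguinity and the CNV cross-check."""

import itertools
import random

import pytest

from varprio import (
    RohParams,
    build_cnv_index,
    cnv_crosscheck,
    compound_het_pairs,
    detect_roh,
    infer_consanguinity,
    segregate,
    simulate_first_cousin_offspring,
)
from varprio.inheritance import RohSegment
from varprio.models_io import CnvCall, GenotypeCall, PedMember, Pedigree, VariantRecord

from oracles import (
    mosaic_expected,
    mt_expected,
    overlaps_naive,
    roh_segments_bruteforce,
    trio_autosomal_expected,
    xl_expected,
)


def make_trio(index_sex="male", mother_affected=False):
    return Pedigree("FAM1", [
        PedMember("IDX", index_sex, True, "FA", "MO"),
        PedMember("FA", "male", False),
        PedMember("MO", "female", mother_affected),
    ], "IDX")


def make_singleton():
    return Pedigree("FAM1", [PedMember("IDX", "male", True)], "IDX")


def make_variant(contig, gts, af=None):
    genotypes = {}
    for sample, count in gts.items():
        if count is None:
            genotypes[sample] = GenotypeCall(None)
        elif isinstance(count, tuple):  # (count, ploidy)
            genotypes[sample] = GenotypeCall(count[0], ploidy=count[1])
        else:
            genotypes[sample] = GenotypeCall(
                count, allelic_fraction=af if sample == "IDX" else None)
    return VariantRecord(contig, 1000, "A", "T", gene="G1",
                         consequence="missense_variant", genotypes=genotypes)


class TestSegregationTruthTables:
    @pytest.mark.parametrize("model", ["AD-denovo", "AD-inherited", "AR-hom", "AR-comphet"])
    @pytest.mark.parametrize("mother_affected", [False, True])
    def test_all_27_trio_combinations(self, model, mother_affected):
        ped = make_trio(mother_affected=mother_affected)
        for i, f, m in itertools.product(range(3), repeat=3):
            v = make_variant("1", {"IDX": i, "FA": f, "MO": m}, af=0.5)
            verdict = segregate(v, ped, model)
            expected = trio_autosomal_expected(model, i, f, m, mother_affected)
            assert verdict.consistent == expected, (model, i, f, m, verdict.reason)
            if not verdict.consistent:
                assert verdict.reason

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_x_linked_combinations(self, sex):
        ped = make_trio(index_sex=sex)
        idx_counts = [(0, 1), (1, 1)] if sex == "male" else [(0, 2), (1, 2), (2, 2)]
        for (i, ip), (f, fp), m in itertools.product(
                idx_counts, [(0, 1), (1, 1)], range(3)):
            v = make_variant("X", {"IDX": (i, ip), "FA": (f, fp), "MO": m})
            verdict = segregate(v, ped, "XL")
            assert verdict.consistent == xl_expected(sex, i, f), (sex, i, f, m)

    def test_xl_requires_x_contig(self):
        v = make_variant("1", {"IDX": 1, "FA": 0, "MO": 0})
        assert not segregate(v, make_trio(), "XL").consistent

    def test_mitochondrial(self):
        ped = make_trio()
        for i in (0, 1):
            v = make_variant("MT", {"IDX": (i, 1), "FA": (0, 1), "MO": (1, 1)})
            assert segregate(v, ped, "MT").consistent == mt_expected(i)

    @pytest.mark.parametrize("count,af", [(1, 0.12), (1, 0.29), (1, 0.30), (1, None), (0, 0.1)])
    def test_mosaic_flag(self, count, af):
        ped = make_trio()
        v = make_variant("1", {"IDX": count, "FA": 0, "MO": 0}, af=af)
        assert segregate(v, ped, "mosaic-candidate").consistent == \
            mosaic_expected(count, af)

    def test_singleton_unconstrained_for_every_model(self):
        ped = make_singleton()
        v = make_variant("1", {"IDX": 1})
        for model in ("AD-denovo", "AD-inherited", "AR-hom", "AR-comphet",
                      "XL", "MT", "mosaic-candidate"):
            verdict = segregate(v, ped, model)
            assert verdict.consistent
            assert "unconstrained" in verdict.reason

    def test_uncalled_index_inconsistent(self):
        v = make_variant("1", {"IDX": None, "FA": 0, "MO": 0})
        verdict = segregate(v, make_trio(), "AD-denovo")
        assert not verdict.consistent and "index uncalled" in verdict.reason

    def test_uncalled_parent_cannot_confirm_de_novo(self):
        v = make_variant("1", {"IDX": 1, "FA": None, "MO": 0})
        verdict = segregate(v, make_trio(), "AD-denovo")
        assert not verdict.consistent and "cannot confirm" in verdict.reason

    def test_reduced_penetrance_switch(self):
        ped = make_trio(mother_affected=True)
        v = make_variant("1", {"IDX": 1, "FA": 1, "MO": 1})
        assert not segregate(v, ped, "AD-inherited").consistent
        assert segregate(v, ped, "AD-inherited",
                         allow_reduced_penetrance=True).consistent

    def test_unknown_model_fatal(self):
        v = make_variant("1", {"IDX": 1, "FA": 0, "MO": 0})
        with pytest.raises(ValueError, match="unknown segregation model"):
            segregate(v, make_trio(), "AD-weird")


def _gene_variant(pos, gts):
    genotypes = {s: GenotypeCall(c) if c is not None else GenotypeCall(None)
                 for s, c in gts.items()}
    return VariantRecord("1", pos, "A", "T", gene="G1",
                         consequence="missense_variant", genotypes=genotypes)


class TestCompoundHet:
    def test_trans_pair_by_parental_origin(self):
        ped = make_trio()
        v1 = _gene_variant(100, {"IDX": 1, "FA": 1, "MO": 0})
        v2 = _gene_variant(200, {"IDX": 1, "FA": 0, "MO": 1})
        (pair,) = compound_het_pairs([v1, v2], ped)
        assert pair.phase == "trans"

    def test_cis_pair_rejected(self):
        ped = make_trio()
        v1 = _gene_variant(100, {"IDX": 1, "FA": 0, "MO": 1})
        v2 = _gene_variant(200, {"IDX": 1, "FA": 0, "MO": 1})
        assert compound_het_pairs([v1, v2], ped) == []

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_singleton_all_pairs_phase_unknown(self, k):
        from oracles import comphet_pair_count_unphased

        ped = make_singleton()
        variants = [_gene_variant(100 + i, {"IDX": 1}) for i in range(k)]
        pairs = compound_het_pairs(variants, ped)
        assert len(pairs) == comphet_pair_count_unphased(k)
        assert all(p.phase == "unknown" for p in pairs)

    def test_hom_variants_never_pair(self):
        ped = make_singleton()
        variants = [_gene_variant(100, {"IDX": 2}), _gene_variant(200, {"IDX": 1})]
        assert compound_het_pairs(variants, ped) == []


class TestDetectRoh:
    def _sites(self, positions, counts, contig="1"):
        return [(contig, p, c) for p, c in zip(positions, counts)]

    def test_long_hom_run_detected(self):
        positions = [i * 40_000 + 1 for i in range(30)]  # spans 1.16 Mb
        segs = detect_roh("E1", self._sites(positions, [0] * 30))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end, seg.n_sites) == (1, 29 * 40_000 + 1, 30)
        assert seg.length_bp > 1_000_000

    def test_short_run_rejected_by_length_floor(self):
        positions = [i * 27_000 + 1 for i in range(30)]  # spans 0.78 Mb
        assert detect_roh("E1", self._sites(positions, [0] * 30)) == []

    def test_het_budget_splits_runs(self):
        # two 26-site hom runs separated by 2 hets never merge at max_het=1
        counts = [0] * 26 + [1, 1] + [0] * 26
        positions = [i * 50_000 + 1 for i in range(len(counts))]
        segs = detect_roh("E1", self._sites(positions, counts))
        assert len(segs) == 2
        assert all(s.n_het_used == 0 for s in segs)

    def test_single_het_tolerated_inside_run(self):
        counts = [0] * 15 + [1] + [0] * 15
        positions = [i * 50_000 + 1 for i in range(len(counts))]
        (seg,) = detect_roh("E1", self._sites(positions, counts))
        assert seg.n_sites == 31 and seg.n_het_used == 1

    def test_unsorted_input_fatal(self):
        with pytest.raises(ValueError, match="sorted"):
            detect_roh("E1", [("1", 500, 0), ("1", 100, 0)])

    def test_matches_bruteforce_scan(self):
        rng = random.Random(11)
        params = RohParams(min_length_bp=200_000, min_sites=8, max_het=1)
        for _ in range(40):
            n = rng.randint(20, 120)
            positions = sorted(rng.sample(range(1, 3_000_000), n))
            counts = [rng.choices([0, 1, 2], weights=[5, 2, 2])[0] for _ in range(n)]
            segs = detect_roh("E1", self._sites(positions, counts), params)
            expected = roh_segments_bruteforce(
                positions, counts, params.min_length_bp, params.min_sites, params.max_het)
            assert [(s.start, s.end, s.n_sites) for s in segs] == expected

    def test_segments_non_overlapping(self):
        rng = random.Random(2)
        params = RohParams(min_length_bp=100_000, min_sites=5, max_het=1)
        positions = sorted(rng.sample(range(1, 2_000_000), 150))
        counts = [rng.choices([0, 1], weights=[8, 1])[0] for _ in positions]
        segs = detect_roh("E1", self._sites(positions, counts), params)
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start


class TestFroh:
    def _seg(self, start, end):
        return RohSegment("E1", "1", start, end, 30, 0)

    def test_no_segments(self):
        froh, consang = infer_consanguinity([], 20_000_000)
        assert froh == 0.0 and not consang

    def test_ten_percent_coverage(self):
        froh, consang = infer_consanguinity([self._seg(1, 2_000_000)], 20_000_000)
        assert froh == pytest.approx(0.10) and consang

    def test_monotone_and_bounded(self):
        segs = []
        prev = 0.0
        for i in range(10):
            segs.append(self._seg(i * 2_000_000 + 1, i * 2_000_000 + 1_500_000))
            froh, _ = infer_consanguinity(segs, 20_000_000)
            assert 0.0 <= froh <= 1.0 and froh >= prev
            prev = froh

    def test_first_cousin_offspring_recovery(self):
        # expected inbreeding coefficient F = 1/16 for first-cousin parents
        vals = []
        for seed in range(5):
            sites, _, autosome_length = simulate_first_cousin_offspring(seed)
            segs = detect_roh("E1", sites)
            froh, _ = infer_consanguinity(segs, autosome_length)
            vals.append(froh)
        assert abs(sum(vals) / len(vals) - 0.0625) <= 0.02


class TestCnvCrosscheck:
    def test_hom_variant_inside_het_deletion(self):
        index = build_cnv_index([CnvCall("E1", "1", 500, 1500, "deletion-het")])
        assert cnv_crosscheck("1", 1000, "E1", index) == "suspect"

    def test_no_calls_is_clear(self):
        assert cnv_crosscheck("1", 1000, "E1", build_cnv_index([])) == "clear"

    def test_other_experiment_or_state_ignored(self):
        calls = [CnvCall("E2", "1", 500, 1500, "deletion-het"),
                 CnvCall("E1", "1", 500, 1500, "duplication")]
        assert cnv_crosscheck("1", 1000, "E1", build_cnv_index(calls)) == "clear"

    def test_matches_interval_overlap_oracle(self):
        rng = random.Random(23)
        raw = []
        for _ in range(100):
            start = rng.randint(1, 900_000)
            raw.append((f"E{rng.randint(1, 5)}", str(rng.randint(1, 2)),
                        start, start + rng.randint(100, 50_000),
                        rng.choice(["deletion-het", "deletion-hom", "duplication"])))
        index = build_cnv_index([CnvCall(*c) for c in raw])
        for _ in range(1000):
            contig, pos = str(rng.randint(1, 2)), rng.randint(1, 1_000_000)
            exp = f"E{rng.randint(1, 5)}"
            expected = "suspect" if overlaps_naive(contig, pos, exp, raw) else "clear"
            assert cnv_crosscheck(contig, pos, exp, index) == expected
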