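"""Filter stack, het-AR flagging, case-status registry, year binning and
cohort summaries."""

import random

import pytest

from varprio import (
    CandidateRow,
    CaseBundle,
    CaseRegistry,
    FilterConfig,
    derive_summary_stats,
    flag_het_ar_candidates,
    load_run_config,
    reanalyse_cohort,
    run_filter_stack,
    summarize_cohort,
    tag_case_status,
    year_bin_causatives,
)
from varprio.engine import _passes_filters, round_half_up
from varprio.knowledge import GeneDiseaseAssociation, KnowledgeBase
from varprio.models_io import (
    GenePanel,
    GenotypeCall,
    PedMember,
    Pedigree,
    PhenotypeRecord,
    VariantRecord,
)


def _trio():
    return Pedigree("FAM1", [
        PedMember("IDX", "male", True, "FA", "MO"),
        PedMember("FA", "male", False),
        PedMember("MO", "female", False),
    ], "IDX")


def _variant(pos=100, gene="G1", af_ext=1e-4, af_int=0.005, plp=True,
             idx_count=1, fa=0, mo=0, contig="1"):
    v = VariantRecord(contig, pos, "A", "T", gene=gene, consequence="missense_variant",
                      genotypes={"IDX": GenotypeCall(idx_count, allelic_fraction=0.5),
                                 "FA": GenotypeCall(fa), "MO": GenotypeCall(mo)})
    v.af_external = af_ext
    v.af_internal = af_int
    v.is_plp = plp
    v.clinical_significance = "pathogenic" if plp else "benign"
    return v


def _bundle(variants, panel_genes=("G1",)):
    return CaseBundle(
        pedigree=_trio(),
        phenotype=PhenotypeRecord(experiment_id="IDX", ern_tag="RND"),
        variants=variants,
        panel=GenePanel("p", "ERN-curated", set(panel_genes)),
    )


class TestFilterStack:
    def test_planted_pathogenic_variant_survives(self):
        rows = run_filter_stack(_bundle([_variant()]), KnowledgeBase(), FilterConfig())
        assert len(rows) == 1
        assert rows[0].status == "candidate"
        assert "AD-denovo=yes" in rows[0].segregation

    @pytest.mark.parametrize("kw", [
        dict(af_ext=0.02),            # fails gnomAD-style rarity (< 0.01)
        dict(af_int=0.03),            # fails internal cohort rarity (< 0.02)
        dict(gene="OTHER"),           # not in the panel
        dict(plp=False),              # no P/LP assertion
        dict(idx_count=0),            # index carries no alternate allele
    ])
    def test_each_criterion_excludes(self, kw):
        rows = run_filter_stack(_bundle([_variant(**kw)]), KnowledgeBase(), FilterConfig())
        assert rows == []

    def test_threshold_is_strict_inequality(self):
        rows = run_filter_stack(
            _bundle([_variant(af_ext=0.01)]), KnowledgeBase(), FilterConfig())
        assert rows == []

    def test_empty_panel_skips_case(self, caplog):
        bundle = _bundle([_variant()], panel_genes=())
        with caplog.at_level("WARNING", logger="varprio"):
            assert run_filter_stack(bundle, KnowledgeBase(), FilterConfig()) == []
        assert "skipped" in caplog.text

    def test_conjunction_is_order_independent(self):
        """The stack is a pure predicate: its result equals the conjunction of
        individually-evaluated filters, in any order."""
        rng = random.Random(4)
        config = FilterConfig()
        bundle = _bundle([], panel_genes=("G1", "G2"))
        for _ in range(200):
            v = _variant(
                pos=rng.randint(1, 10_000),
                gene=rng.choice(["G1", "G2", "G3"]),
                af_ext=rng.choice([0.0, 1e-4, 0.02, 0.3]),
                af_int=rng.choice([0.0, 0.005, 0.05]),
                plp=rng.random() < 0.5,
                idx_count=rng.randint(0, 2))
            checks = [
                v.af_external < config.af_external_max,
                v.af_internal < config.af_internal_max,
                v.gene in bundle.panel.genes,
                v.is_plp,
                v.genotypes["IDX"].carries_alt,
            ]
            rng.shuffle(checks)
            assert _passes_filters(v, bundle, config) == all(checks)

    def test_monotone_in_threshold_and_panel(self, small_cohort):
        config = load_run_config(small_cohort.config_path)
        base = reanalyse_cohort(config)
        tight = load_run_config(small_cohort.config_path)
        tight.filters = FilterConfig(af_external_max=0.0005)
        tight_run = reanalyse_cohort(tight)
        base_keys = {(r.case_id, r.variant_key) for r in base.rows}
        tight_keys = {(r.case_id, r.variant_key) for r in tight_run.rows}
        assert tight_keys <= base_keys

    def test_segregation_annotates_but_does_not_filter(self):
        # inconsistent with every model, still reported
        v = _variant(idx_count=1, fa=1, mo=1)
        rows = run_filter_stack(_bundle([v]), KnowledgeBase(), FilterConfig())
        assert len(rows) == 1
        assert "AD-denovo=no" in rows[0].segregation
        hard = FilterConfig(segregation_filter=True,
                            segregation_models=("AD-denovo",))
        assert run_filter_stack(_bundle([v]), KnowledgeBase(), hard) == []


def _ar_kb():
    kb = KnowledgeBase()
    kb.gene2disease = {
        "ARG": [GeneDiseaseAssociation("ARG", "OMIM:1", "AR", 2000)],
        "ADG": [GeneDiseaseAssociation("ADG", "OMIM:2", "AD", 2000)],
    }
    return kb


def _row(case="FAM1", pos=100, gene="ARG", gt="0/1", status="candidate"):
    return CandidateRow(case_id=case, contig="1", pos=pos, ref="A", alt="T",
                        gene=gene, genotype_index=gt, status=status)


class TestHetArFlagging:
    def test_lone_het_in_recessive_gene_flagged(self):
        rows = flag_het_ar_candidates([_row()], _ar_kb())
        assert rows[0].status == "het_AR_candidate"

    def test_two_hets_in_gene_stay_candidates(self):
        rows = flag_het_ar_candidates([_row(pos=100), _row(pos=200)], _ar_kb())
        assert [r.status for r in rows] == ["candidate", "candidate"]

    def test_hom_or_dominant_gene_not_flagged(self):
        rows = flag_het_ar_candidates(
            [_row(gt="1/1"), _row(pos=300, gene="ADG"), _row(pos=400, gene="NOV")],
            _ar_kb())
        assert all(r.status == "candidate" for r in rows)


class TestRegistryAndTagging:
    def test_solve_one_of_two_rows(self):
        registry = CaseRegistry()
        rows = [_row(pos=100), _row(pos=200)]
        tag_case_status(registry, "FAM1", "solved",
                        variant_keys=["1:100:A:T"], case_rows=rows)
        assert rows[0].status == "solved" and rows[1].status == "rejected"
        assert registry.is_solved("FAM1")

    def test_solving_with_foreign_key_fatal(self):
        with pytest.raises(ValueError, match="not among its rows"):
            tag_case_status(CaseRegistry(), "FAM1", "solved",
                            variant_keys=["9:9:G:C"], case_rows=[_row()])

    def test_registry_equals_event_replay(self):
        rng = random.Random(8)
        registry = CaseRegistry()
        expected = {}
        for step in range(60):
            case = f"FAM{rng.randint(1, 10)}"
            decision = rng.choice(["solved", "under_evaluation", "unsolved"])
            keys = ["1:100:A:T"] if decision == "solved" else None
            rows = [_row(case=case)] if decision == "solved" else None
            tag_case_status(registry, case, decision, keys, rows)
            expected[case] = decision  # independent last-write-wins bookkeeping
        assert {c: s["status"] for c, s in registry.cases.items()} == expected
        assert registry.cases == CaseRegistry.replay(registry.events)

    def test_registry_round_trip(self, tmp_path):
        registry = CaseRegistry()
        tag_case_status(registry, "FAM1", "under_evaluation")
        registry.save(tmp_path / "reg.json")
        assert CaseRegistry.load(tmp_path / "reg.json").cases == registry.cases

    def test_solved_cases_skipped_on_rerun(self, small_cohort, tmp_path):
        config = load_run_config(small_cohort.config_path)
        first = reanalyse_cohort(config)
        solved_case = first.rows[0].case_id
        registry = CaseRegistry()
        tag_case_status(registry, solved_case, "solved",
                        variant_keys=[first.rows[0].variant_key],
                        case_rows=[r for r in first.rows if r.case_id == solved_case])
        registry.save(config.registry)
        try:
            second = reanalyse_cohort(config)
            assert second.n_processed == first.n_processed - 1
            assert solved_case in second.manifest["skipped_solved"]
            config.include_solved = True
            third = reanalyse_cohort(config)
            assert third.n_processed == first.n_processed
        finally:
            config.registry.unlink()


class TestYearBins:
    @pytest.mark.parametrize("year,expected", [
        (2018, ">=2017"), (2017, ">=2017"), (2016, "2015-2016"),
        (2012, "2010-2014"), (1999, "<2010"), (None, "unknown"),
    ])
    def test_bin_assignment(self, year, expected):
        row = _row()
        row.first_association_year = year
        bins = year_bin_causatives([row])
        assert bins[expected]["gene_count"] == 1

    def test_empty_input_all_zero(self):
        bins = year_bin_causatives([])
        assert all(b["gene_count"] == 0 and b["variant_count"] == 0
                   for b in bins.values())

    def test_matches_direct_tally(self):
        rng = random.Random(31)
        rows = []
        for _ in range(124):
            r = _row(pos=rng.randint(1, 10**6))
            r.first_association_year = rng.choice([2018, 2016, 2012, 1999, None])
            r.first_plp_year = rng.choice([2019, 2015, 2010, 2005])
            rows.append(r)
        bins = year_bin_causatives(rows)
        tally = {}
        for r in rows:
            y = r.first_association_year
            label = ("unknown" if y is None else ">=2017" if y >= 2017
                     else "2015-2016" if y >= 2015 else "2010-2014" if y >= 2010
                     else "<2010")
            tally[label] = tally.get(label, 0) + 1
        for label, count in tally.items():
            assert bins[label]["gene_count"] == count
            assert bins[label]["gene_pct"] == round_half_up(100 * count / 124, 1)


class TestSummaries:
    def test_published_cohort_arithmetic(self):
        stats = derive_summary_stats(
            total_cases=4411, candidate_variants=2593, cases_with_candidates=1785,
            prioritised_variants=678, prioritised_cases=566, solved_cases=120)
        assert stats["mean_candidates_per_case"] == pytest.approx(1.45)
        assert stats["mean_prioritised_per_case"] == pytest.approx(1.20)
        assert stats["pct_prioritised_cases_of_candidate_cases"] == pytest.approx(31.7)
        assert stats["pct_solved_of_prioritised"] == pytest.approx(21.2)
        assert stats["pct_solved_of_total"] == pytest.approx(2.7)

    def test_summary_reconciles_with_rows(self, small_run):
        config, run = small_run
        total = run.summary.total
        assert total["n_cases_with_candidates"] == len({r.case_id for r in run.rows})
        assert total["n_candidate_variants"] == len(run.rows)
        for key in ("n_cases", "n_trio", "n_singleton", "n_other",
                    "n_candidate_variants", "n_solved", "n_unsolved"):
            assert sum(b[key] for b in run.summary.per_ern.values()) == total[key]
        # the four case-level statuses partition the analysed cases
        assert (total["n_solved"] + total["n_under_evaluation"]
                + total["n_het_ar_cases"] + total["n_unsolved"]) == total["n_cases"]
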