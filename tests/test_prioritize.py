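"""Panel intersection, MOI filtering, ranking, cohort summary, comparison."""

import random

import pytest

from phenopanel.acmg import combine_criteria, parse_criteria
from phenopanel.prioritize import (
    CaseProfile,
    MOICatalog,
    PrioritizedVariant,
    annotate_hpo_match,
    compare_panels,
    filter_mode_of_inheritance,
    flag_age_compatibility,
    intersect_panel,
    prioritize_case,
    rank_candidates,
    summarize_cohort,
)
from phenopanel.reference import reference_cohort, reference_prioritized
from phenopanel.variant_filter import HET, HOM_ALT, VariantRecord


def _rec(pos, gene, genotype=HET, **kw):
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="G", genotype=genotype, gene=gene,
        depth=60, genotype_quality=90, **kw,
    )


def _case(case_id="c1", value=30.0, unit="years"):
    return CaseProfile(
        case_id=case_id, age_value=value, age_unit=unit,
        hpo_terms=frozenset({"HP:0000002"}),
    )


def _pv(pos, tier, moi="consistent", matches=(), simscore=None, gene="G",
        consequence="missense_variant", genotype=HET):
    crit = {5: "PVS1, PS1", 4: "PVS1, PM2", 3: "PM2"}[tier]
    return PrioritizedVariant(
        record=_rec(pos, gene, genotype=genotype, consequence=consequence,
                    acmg_criteria=crit),
        hpo_matches=frozenset(matches),
        acmg=combine_criteria(parse_criteria(crit)),
        moi_verdict=moi,
        simscore=simscore,
    )


class TestIntersectPanel:
    def test_worked_fixture_partition(self, worked_fixture, default_config):
        records, panel, catalog, _ = worked_fixture
        from phenopanel.variant_filter import run_first_filter_block

        kept, _ = run_first_filter_block(
            list(records.values()), default_config, catalog.frequency_context()
        )
        in_panel, out = intersect_panel(kept, panel)
        assert {r.pos for r in in_panel} == {500, 700, 800}  # v5, v7, v8
        assert [r.pos for r, _ in out] == [600]  # v6 out of panel

    def test_empty_panel_all_out(self, toy_graph, toy_annotations):
        from phenopanel.ontology import VirtualPanel

        empty = VirtualPanel(frozenset(), frozenset(), {})
        recs = [_rec(1, "G1"), _rec(2, None)]
        in_panel, out = intersect_panel(recs, empty)
        assert in_panel == [] and len(out) == 2
        assert dict((r.pos, why) for r, why in out) == {1: "not_in_panel", 2: "no_gene"}


class TestHpoMatchAnnotation:
    def test_multi_seed_provenance(self, toy_graph, toy_annotations):
        from phenopanel.ontology import build_virtual_panel

        panel = build_virtual_panel(
            toy_graph, toy_annotations, ["HP:0000002", "HP:0000004"]
        )
        # G4 is annotated under both branches
        assert annotate_hpo_match(_rec(1, "G4"), panel) == {
            "HP:0000002",
            "HP:0000004",
        }
        assert annotate_hpo_match(_rec(2, "G2"), panel) == {"HP:0000002"}

    def test_out_of_panel_is_error(self, toy_panel):
        with pytest.raises(ValueError):
            annotate_hpo_match(_rec(1, "G3"), toy_panel)


class TestMOIFilter:
    catalog = MOICatalog(
        {
            "ADG": {"autosomal_dominant"},
            "ARG": {"autosomal_recessive"},
            "XLG": {"x_linked"},
        }
    )

    def test_homozygous_recessive_consistent(self):
        v = _rec(1, "ARG", genotype=HOM_ALT)
        assert filter_mode_of_inheritance([v], self.catalog)[v] == "consistent"

    def test_single_het_recessive_only_inconsistent(self):
        v = _rec(1, "ARG")
        assert filter_mode_of_inheritance([v], self.catalog)[v] == "inconsistent"

    def test_two_hets_flagged_possible_compound_het(self):
        v1, v2 = _rec(1, "ARG"), _rec(2, "ARG")
        verdicts = filter_mode_of_inheritance([v1, v2], self.catalog)
        assert verdicts[v1] == verdicts[v2] == "possible_compound_het"

    def test_het_dominant_consistent(self):
        v = _rec(1, "ADG")
        assert filter_mode_of_inheritance([v], self.catalog)[v] == "consistent"

    def test_unknown_gene_retained_as_unknown(self):
        v = _rec(1, "MYSTERY")
        assert filter_mode_of_inheritance([v], self.catalog)[v] == "unknown"

    def test_hemizygous_x_linked_consistent(self):
        v = _rec(1, "XLG", genotype="hemi")
        assert filter_mode_of_inheritance([v], self.catalog)[v] == "consistent"


class TestRanking:
    def test_higher_tier_first(self):
        tier4 = _pv(100, 4)
        tier3 = _pv(50, 3, matches={"HP:0000002"})
        ranked = rank_candidates([tier3, tier4])
        assert [v.record.pos for v in ranked] == [100, 50]
        assert [v.rank for v in ranked] == [1, 2]

    def test_simscore_breaks_ties(self):
        a = _pv(100, 3, simscore=0.2)
        b = _pv(200, 3, simscore=0.9)
        ranked = rank_candidates([a, b])
        assert [v.record.pos for v in ranked] == [200, 100]

    def test_inconsistent_listed_last_despite_tier(self):
        bad = _pv(100, 4, moi="inconsistent")
        ok = _pv(200, 3)
        ranked = rank_candidates([bad, ok])
        assert [v.record.pos for v in ranked] == [200, 100]

    def test_order_invariant_to_input_permutation(self):
        pool = [
            _pv(100, 4), _pv(200, 3, matches={"a"}), _pv(300, 3),
            _pv(400, 3, moi="unknown"), _pv(500, 3, simscore=0.4),
        ]
        rnd = random.Random(0)
        reference = [v.record.pos for v in rank_candidates(pool)]
        for _ in range(5):
            shuffled = pool[:]
            rnd.shuffle(shuffled)
            assert [v.record.pos for v in rank_candidates(shuffled)] == reference


class TestAgeFlag:
    def test_adult_onset_gene_in_infant_atypical(self):
        v = _pv(1, 3, gene="DSG2L")
        infant = _case(value=8.0, unit="months")
        assert flag_age_compatibility(v, infant, {"DSG2L": "adult"}) == "atypical"

    def test_empty_onset_map_unassessed(self):
        assert flag_age_compatibility(_pv(1, 3), _case(), None) == "unassessed"

    def test_matching_onset_compatible(self):
        v = _pv(1, 3, gene="ADULTG")
        assert flag_age_compatibility(v, _case(), {"ADULTG": "adult"}) == "compatible"


class TestCaseProfile:
    def test_age_class_boundary(self):
        assert _case(value=9.0, unit="months").age_class == "infant"
        assert _case(value=23.0, unit="years").age_class == "adult"
        assert _case(value=4.0, unit="weeks").age_class == "infant"

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            CaseProfile("x", 1.0, "years", frozenset())


class TestCohortSummary:
    def test_reference_series_counts(self):
        per_case = reference_prioritized()
        part_a = {
            cid: [v for v in vs if not v.rescued] for cid, vs in per_case.items()
        }
        summary = summarize_cohort(part_a, reference_cohort())
        assert summary.total_candidates == 11
        assert summary.matches_per_seed["HP:0011675"] == 4  # arrhythmia
        assert summary.matches_per_seed["HP:0001645"] == 7  # sudden cardiac death
        assert summary.matches_per_seed["HP:0002133"] == 2  # status epilepticus
        assert summary.matches_per_seed["HP:0002104"] == 1  # apnea
        assert summary.per_type["missense"] == 9
        assert summary.per_type["splice"] == 2
        assert summary.infants_with_candidate == 6
        assert summary.adults_with_candidate == 3
        assert summary.n_infants == 7 and summary.n_adults == 9

    def test_empty_cohort_all_zero(self):
        summary = summarize_cohort({}, [])
        assert summary.total_candidates == 0
        assert summary.infants_with_candidate == 0
        assert summary.mean_candidates_per_case == 0.0


class TestComparePanels:
    def test_virtual_only_variant_listed(self, toy_annotations):
        upb1_like = _pv(700, 4, gene="UPB1L")
        shared = _pv(100, 3, gene="G1")
        report = compare_panels([upb1_like, shared], [shared], ["G1", "G9"],
                                toy_annotations)
        assert report.virtual_only == {upb1_like.record.key}
        assert report.both == {shared.record.key}
        assert report.uncovered_fixed_genes == {"G9"}

    def test_identical_candidate_sets(self):
        pv = _pv(1, 3)
        report = compare_panels([pv], [pv], [])
        assert report.virtual_only == report.fixed_only == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_identity(self, seed):
        rnd = random.Random(seed)
        pool = [_pv(i * 10, 3) for i in range(1, 12)]
        v = [p for p in pool if rnd.random() < 0.6]
        f = [p for p in pool if rnd.random() < 0.6]
        report = compare_panels(v, f, [])
        union = {p.record.key for p in v} | {p.record.key for p in f}
        assert len(report.both) + len(report.virtual_only) + len(
            report.fixed_only
        ) == len(union)


class TestPrioritizeCase:
    def test_worked_fixture_end_to_end(self, worked_fixture, default_config):
        records, panel, catalog, _ = worked_fixture
        candidates, report = prioritize_case(
            list(records.values()), panel, _case(), default_config, catalog
        )
        # v5 (dominant missense) and v7 (homozygous recessive splice) survive;
        # v6 is out of panel, v8 is a single het in a recessive-only gene
        assert {v.record.pos for v in candidates} == {500, 700}
        assert report.counts["candidates"] == 2
        assert report.reconciles()
        # the likely-pathogenic homozygous splice variant outranks the VUS
        assert candidates[0].record.pos == 700
        assert candidates[0].acmg.tier == 4
        assert candidates[0].moi_verdict == "consistent"

    def test_funnel_monotone(self, worked_fixture, default_config):
        records, panel, catalog, _ = worked_fixture
        _, report = prioritize_case(
            list(records.values()), panel, _case(), default_config, catalog
        )
        counts = [report.counts[s] for s in report.STAGES if s in report.counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
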