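"""VCF I/O and the first filter block (quality/frequency/impact/benign)."""

import itertools
import random

import pytest

from phenopanel.variant_filter import (
    HET,
    HOM_ALT,
    FilterConfig,
    VariantRecord,
    VcfParseError,
    exclude_known_benign,
    filter_consequence,
    filter_frequency,
    filter_quality,
    read_annotated_vcf,
    run_first_filter_block,
    write_vcf,
)

VCF_FIXTURE = """##fileformat=VCFv4.2
##contig=<ID=1,length=250000000>
##INFO=<ID=GENE,Number=1,Type=String,Description="g">
##INFO=<ID=CSQ,Number=1,Type=String,Description="c">
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="af">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\t.\tA\tG\t.\tPASS\tGENE=GENE1;CSQ=missense_variant;GNOMAD_AF=0.0001\tGT:DP:GQ\t0/1:50:99
1\t200\t.\tC\tT,G\t.\tPASS\tGENE=GENE2;CSQ=missense_variant;GNOMAD_AF=0.001,0.002\tGT:DP:GQ\t1/2:40:80
1\t300\t.\tG\tA\t.\tPASS\tGENE=GENE3;CSQ=synonymous_variant\tGT:DP:GQ\t1/1:60:90
"""


class TestReadVcf:
    def test_multiallelic_split_yields_four_records(self, tmp_path):
        path = tmp_path / "fixture.vcf"
        path.write_text(VCF_FIXTURE)
        records = read_annotated_vcf(str(path))
        assert len(records) == 4
        site2 = [r for r in records if r.pos == 200]
        assert {r.alt for r in site2} == {"T", "G"}
        assert all(r.genotype == HET for r in site2)
        assert sorted(r.gnomad_af for r in site2) == pytest.approx([0.001, 0.002])

    def test_missing_af_is_absent_not_zero(self, tmp_path):
        path = tmp_path / "fixture.vcf"
        path.write_text(VCF_FIXTURE)
        records = read_annotated_vcf(str(path))
        site3 = next(r for r in records if r.pos == 300)
        assert site3.gnomad_af is None
        assert site3.genotype == HOM_ALT

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_FIXTURE + "1\tnotanumber\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(VcfParseError, match="line 13"):
            read_annotated_vcf(str(path))

    def test_sidecar_annotations_override(self, tmp_path):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(VCF_FIXTURE)
        side = tmp_path / "side.tsv"
        side.write_text(
            "chrom\tpos\tref\talt\tacmg_criteria\n1\t100\tA\tG\tPM2, PP3\n"
        )
        records = read_annotated_vcf(str(vcf), sidecar=str(side))
        r100 = next(r for r in records if r.pos == 100)
        assert r100.acmg_criteria == "PM2, PP3"

    def test_sidecar_duplicate_key_rejected(self, tmp_path):
        from phenopanel.variant_filter import SidecarFormatError

        vcf = tmp_path / "s.vcf"
        vcf.write_text(VCF_FIXTURE)
        side = tmp_path / "side.tsv"
        side.write_text(
            "chrom\tpos\tref\talt\tgene\n1\t100\tA\tG\tX\n1\t100\tA\tG\tY\n"
        )
        with pytest.raises(SidecarFormatError, match="duplicate"):
            read_annotated_vcf(str(vcf), sidecar=str(side))


def random_records(seed, n=25):
    rnd = random.Random(seed)
    out = []
    for i in range(n):
        out.append(
            VariantRecord(
                chrom="1",
                pos=100 + i * 7,
                ref="A",
                alt=rnd.choice(["T", "C", "G"]),
                genotype=rnd.choice([HET, HOM_ALT]),
                depth=rnd.randrange(0, 120),
                genotype_quality=rnd.randrange(0, 100),
                gene=rnd.choice(["GA", "GB", None]),
                consequence=rnd.choice(
                    ["missense_variant", "synonymous_variant", "stop_gained", None]
                ),
                gnomad_af=rnd.choice([None, 1e-5, 3e-4, 1.5e-3, 0.2]),
                clinvar_sig=rnd.choice([None, "Benign", "Pathogenic"]),
                insilico_rank=rnd.choice([None, 0.9]),
                hgvs_c=rnd.choice([None, "c.101A>T"]),
                acmg_criteria=rnd.choice([None, "PM2, PP3"]),
            )
        )
    return out


class TestVcfRoundTrip:
    @pytest.mark.parametrize("seed", range(4))
    def test_write_then_read_preserves_fields(self, tmp_path, seed):
        records = random_records(seed)
        path = tmp_path / "rt.vcf"
        write_vcf(records, str(path))
        back = read_annotated_vcf(str(path))
        original = {r.key: r for r in records}
        assert len(back) == len(records)
        for r in back:
            o = original[r.key]
            assert r.genotype == o.genotype
            assert r.depth == o.depth
            assert r.genotype_quality == o.genotype_quality
            assert r.gene == o.gene
            assert r.consequence == o.consequence
            assert r.gnomad_af == (
                pytest.approx(o.gnomad_af) if o.gnomad_af is not None else None
            )
            assert r.clinvar_sig == o.clinvar_sig
            assert r.hgvs_c == o.hgvs_c
            assert r.acmg_criteria == o.acmg_criteria


def _rec(**kw):
    base = dict(
        chrom="1", pos=10, ref="A", alt="T", genotype=HET,
        depth=60, genotype_quality=90, consequence="missense_variant",
    )
    base.update(kw)
    return VariantRecord(**base)


class TestQualityFilter:
    def test_low_depth_removed_with_reason(self, default_config):
        kept, removed = filter_quality([_rec(depth=10)], default_config)
        assert kept == [] and removed[0][1] == "low_depth"

    def test_zero_thresholds_identity(self):
        cfg = FilterConfig(min_depth=0, min_genotype_quality=0)
        records = [_rec(depth=0, genotype_quality=0), _rec(pos=11)]
        kept, removed = filter_quality(records, cfg)
        assert kept == records and removed == []

    @pytest.mark.parametrize("seed", range(3))
    def test_partition(self, seed, default_config):
        records = random_records(seed)
        kept, removed = filter_quality(records, default_config)
        assert len(kept) + len(removed) == len(records)
        assert set(kept).isdisjoint(r for r, _ in removed)


class TestFrequencyFilter:
    def test_common_removed(self, default_config):
        kept, removed = filter_frequency([_rec(gnomad_af=0.05)], default_config)
        assert kept == [] and removed[0][1] == "common_allele"

    def test_homozygous_recessive_context_retained(self, default_config):
        """A 0.0017889-frequency homozygous splice variant survives in a
        recessive gene context (between the dominant and recessive cutoffs)."""
        rec = _rec(
            gene="UPB1", gnomad_af=0.0017889, genotype=HOM_ALT,
            consequence="splice_acceptor_variant",
        )
        kept, _ = filter_frequency([rec], default_config, {"UPB1": "recessive"})
        assert kept == [rec]
        # same frequency fails in a dominant context
        kept, _ = filter_frequency([rec], default_config, {"UPB1": "dominant"})
        assert kept == []

    def test_two_hets_in_recessive_gene_retained(self, default_config):
        r1 = _rec(pos=10, gene="GAR", gnomad_af=1e-3)
        r2 = _rec(pos=20, gene="GAR", gnomad_af=None)
        kept, _ = filter_frequency([r1, r2], default_config, {"GAR": "recessive"})
        assert set(kept) == {r1, r2}

    def test_absent_af_kept(self, default_config):
        kept, _ = filter_frequency([_rec(gnomad_af=None)], default_config)
        assert len(kept) == 1


class TestConsequenceFilter:
    def test_synonymous_removed(self, default_config):
        kept, removed = filter_consequence(
            [_rec(consequence="synonymous_variant")], default_config
        )
        assert kept == [] and removed[0][1] == "non_qualifying_consequence"

    def test_splice_acceptor_kept(self, default_config):
        kept, _ = filter_consequence(
            [_rec(consequence="splice_acceptor_variant")], default_config
        )
        assert len(kept) == 1

    def test_case_insensitive(self, default_config):
        kept, _ = filter_consequence(
            [_rec(consequence="Missense_Variant")], default_config
        )
        assert len(kept) == 1

    def test_unknown_term_removed_conservatively(self, default_config):
        kept, removed = filter_consequence(
            [_rec(consequence="made_up_term")], default_config
        )
        assert kept == [] and removed[0][1] == "unknown_consequence"
        lax = FilterConfig(drop_unknown_consequence=False)
        kept, _ = filter_consequence([_rec(consequence="made_up_term")], lax)
        assert len(kept) == 1

    def test_keep_all_observed_is_identity(self):
        records = [_rec(consequence=c) for c in
                   ["missense_variant", "synonymous_variant", "intron_variant"]]
        cfg = FilterConfig(
            kept_consequences=frozenset(r.consequence for r in records)
        )
        kept, removed = filter_consequence(records, cfg)
        assert kept == records and removed == []


class TestBenignExclusion:
    def test_likely_benign_removed(self, default_config):
        kept, removed = exclude_known_benign(
            [_rec(clinvar_sig="Likely_benign")], default_config
        )
        assert kept == [] and removed[0][1] == "known_benign"

    def test_conflicting_interpretations_kept(self, default_config):
        kept, _ = exclude_known_benign(
            [_rec(clinvar_sig="Conflicting interpretations of pathogenicity")],
            default_config,
        )
        assert len(kept) == 1

    def test_lovd_class_string_removed(self, default_config):
        kept, _ = exclude_known_benign([_rec(lovd_class="2")], default_config)
        assert kept == []

    def test_absent_labels_kept(self, default_config):
        kept, _ = exclude_known_benign([_rec()], default_config)
        assert len(kept) == 1


class TestFirstFilterBlock:
    def test_worked_example_single_steps(self, worked_fixture, default_config):
        records, panel, catalog, _ = worked_fixture
        kept, report = run_first_filter_block(
            list(records.values()), default_config, catalog.frequency_context()
        )
        assert [report.counts[s] for s in
                ("input", "after_quality", "after_frequency",
                 "after_consequence", "after_benign_exclusion")] == [8, 7, 6, 5, 4]
        assert {r.pos for r in kept} == {500, 600, 700, 800}  # v5..v8
        assert report.reconciles()

    def test_empty_input(self, default_config):
        kept, report = run_first_filter_block([], default_config)
        assert kept == [] and all(v == 0 for v in report.counts.values())

    @pytest.mark.parametrize("seed", range(3))
    def test_final_membership_order_invariant(self, seed, default_config):
        """The four first-block predicates are independent: applying them in
        any order keeps the same final record set."""
        from collections import Counter

        records = random_records(seed, n=40)
        moi = {"GA": "recessive", "GB": "dominant"}
        het_counts = Counter(
            r.gene.lower() for r in records if r.gene and r.genotype == HET
        )
        filters = {
            "q": lambda rs: filter_quality(rs, default_config)[0],
            "f": lambda rs: filter_frequency(rs, default_config, moi, het_counts)[0],
            "c": lambda rs: filter_consequence(rs, default_config)[0],
            "b": lambda rs: exclude_known_benign(rs, default_config)[0],
        }
        reference = None
        for order in itertools.permutations("qfcb"):
            out = records
            for name in order:
                out = filters[name](out)
            result = set(out)
            reference = result if reference is None else reference
            assert result == reference

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_non_increasing_and_reconcile(self, seed, default_config):
        records = random_records(seed, n=60)
        _, report = run_first_filter_block(records, default_config)
        counts = [report.counts[s] for s in report.STAGES if s in report.counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert report.reconciles()


class TestRecordValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            _rec(pos=0)
        with pytest.raises(ValueError):
            _rec(ref="A", alt="A")
        with pytest.raises(ValueError):
            _rec(gnomad_af=1.5)
        with pytest.raises(ValueError):
            _rec(genotype="diploid")
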