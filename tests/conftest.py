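"""Shared fixtures: the 5-term toy ontology and the 8-variant worked example."""

import io

import pytest

from phenopanel.ontology import (
    build_virtual_panel,
    parse_gene_annotations,
    parse_obo,
)
from phenopanel.prioritize import MOICatalog
from phenopanel.variant_filter import HET, HOM_ALT, FilterConfig, VariantRecord

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: cardiac abnormality
is_a: HP:0000001 ! root
alt_id: HP:9000002

[Term]
id: HP:0000003
name: arrhythmia-like
is_a: HP:0000002

[Term]
id: HP:0000004
name: neurological abnormality
is_a: HP:0000001

[Term]
id: HP:0000005
name: seizure-like
is_a: HP:0000004
"""

TOY_ANNOTATIONS = (
    "gene_symbol\thpo_id\n"
    "G1\tHP:0000003\n"
    "G2\tHP:0000002\n"
    "G3\tHP:0000005\n"
    "G4\tHP:0000005\n"
    "G4\tHP:0000003\n"
)


@pytest.fixture(scope="session")
def toy_graph():
    return parse_obo(TOY_OBO)


@pytest.fixture(scope="session")
def toy_annotations(toy_graph):
    return parse_gene_annotations(io.StringIO(TOY_ANNOTATIONS), toy_graph)


@pytest.fixture(scope="session")
def toy_panel(toy_graph, toy_annotations):
    return build_virtual_panel(toy_graph, toy_annotations, ["HP:0000002"])


def _rec(pos, **kw):
    base = dict(
        chrom="1", pos=pos, ref="A", alt="T", genotype=HET,
        depth=60, genotype_quality=90,
    )
    base.update(kw)
    return VariantRecord(**base)


@pytest.fixture()
def worked_fixture(toy_graph):
    """Eight variants single-stepping every rule of the first filter block.

    Panel genes: GENE_AD (dominant), UPB1L (recessive), GENE_AR
    (recessive-only); OUTG is out of panel.
    """
    records = {
        "v1": _rec(100, gene="GENE_AD", consequence="missense_variant",
                   depth=10),
        "v2": _rec(200, gene="GENE_AD", consequence="missense_variant",
                   gnomad_af=0.05),
        "v3": _rec(300, gene="GENE_AD", consequence="synonymous_variant",
                   gnomad_af=1e-5),
        "v4": _rec(400, gene="GENE_AD", consequence="missense_variant",
                   gnomad_af=1e-5, clinvar_sig="Benign"),
        "v5": _rec(500, gene="GENE_AD", consequence="missense_variant",
                   gnomad_af=1e-5, acmg_criteria="PM2, PP3"),
        "v6": _rec(600, gene="OUTG", consequence="missense_variant",
                   gnomad_af=1e-5, acmg_criteria="PM2"),
        "v7": _rec(700, gene="UPB1L", consequence="splice_acceptor_variant",
                   gnomad_af=0.0018, genotype=HOM_ALT,
                   acmg_criteria="PVS1, PM2"),
        "v8": _rec(800, gene="GENE_AR", consequence="frameshift_variant",
                   gnomad_af=1e-5, acmg_criteria="PM2"),
    }
    annotations = parse_gene_annotations(
        io.StringIO(
            "gene_symbol\thpo_id\n"
            "GENE_AD\tHP:0000003\n"
            "UPB1L\tHP:0000002\n"
            "GENE_AR\tHP:0000003\n"
            "OUTG\tHP:0000005\n"
        ),
        toy_graph,
    )
    panel = build_virtual_panel(toy_graph, annotations, ["HP:0000002"])
    catalog = MOICatalog(
        {
            "GENE_AD": {"autosomal_dominant"},
            "UPB1L": {"autosomal_recessive"},
            "GENE_AR": {"autosomal_recessive"},
        }
    )
    return records, panel, catalog, annotations


@pytest.fixture()
def default_config():
    return FilterConfig()
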