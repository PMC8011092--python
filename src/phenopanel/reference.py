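"""Reference candidate-variant series from a published SUD molecular autopsy.

A 16-case sudden-unexplained-death cohort (9 adults aged 23-53 years,
7 infants aged 4 weeks to 9 months) analysed by whole-exome sequencing
with an HPO-driven virtual gene panel reported 13 candidate variants:

* part "a": 11 variants surviving the filter funnel with an exact HPO seed
  match (9 missense, 2 splice-site);
* part "b": 2 additional variants (CTNNA3, KCNA5) found by a fixed
  sudden-death gene panel, with no exact HPO match but a top-range
  phenotype-similarity score.

The rows below transcribe the published per-variant fields: gene, RefSeq
transcript, coding HGVS, amino-acid change, variant type, matched seed
phenotype terms, gnomAD allele frequency, dbSNP id, MetaLR rank, ACMG
criteria string, published 5-tier class, and the decedent's age.  Variants
sharing a published individual accession are attached to the same case
(RYR2+SCN8A; SCN5A c.3152T>C+RBM20; SCN4A+KCNA5).

The six adult cohort members without a candidate variant have no published
ages; :func:`reference_cohort` assigns them synthetic representative ages
evenly spaced inside the stated 23-53-year range (they serve only as
denominators in cohort-level counts).
"""

from __future__ import annotations

from dataclasses import dataclass

from .acmg import combine_criteria, parse_criteria
from .prioritize import CaseProfile, PrioritizedVariant
from .variant_filter import HET, HOM_ALT, VariantRecord

__all__ = [
    "ReferenceVariant",
    "reference_variants",
    "reference_cohort",
    "reference_prioritized",
    "SEED_TERM_BY_NAME",
]

#: Seed phenotype terms by their labels as printed in the variant table.
SEED_TERM_BY_NAME = {
    "arrhythmia": "HP:0011675",
    "sudden cardiac death": "HP:0001645",
    "status epilepticus": "HP:0002133",
    "apnea": "HP:0002104",
}

_TYPE_TO_SO = {
    "missense": "missense_variant",
    "splice donor": "splice_donor_variant",
    "splice acceptor": "splice_acceptor_variant",
}


@dataclass(frozen=True)
class ReferenceVariant:
    """One transcribed row of the reference candidate-variant series."""

    part: str  # "a" = virtual-panel hit, "b" = fixed-panel-only
    case_id: str
    age: str  # as printed, e.g. "8 months"
    gene: str
    nm_accession: str
    hgvs_c: str
    aa_change: str
    variant_type: str
    hpo_match: tuple[str, ...]  # seed term names; empty = no exact match
    gnomad_af: float | None
    dbsnp: str | None
    metalr_rank: float | None
    acmg_criteria: str
    published_class: int
    genotype: str = HET

    @property
    def hpo_match_ids(self) -> frozenset[str]:
        return frozenset(SEED_TERM_BY_NAME[n.lower()] for n in self.hpo_match)

    @property
    def consequence(self) -> str:
        return _TYPE_TO_SO[self.variant_type.lower()]


_ROWS: list[ReferenceVariant] = [
    ReferenceVariant("a", "case_01", "8 months", "DSG2", "NM_001943.4",
                     "c.81+1G>C", "p.(?)", "Splice donor",
                     ("Sudden cardiac death",), None, None, None,
                     "PVS1-m, PM2", 3),
    ReferenceVariant("a", "case_02", "3 months", "UPB1", "NM_016327.2",
                     "c.917-1G>A", "p.(?)", "Splice acceptor",
                     ("Status epilepticus",), 0.0017889, "rs143493067", None,
                     "PVS1, PM2", 4, genotype=HOM_ALT),
    ReferenceVariant("a", "case_03", "4 weeks", "SCN4A", "NM_000334.4",
                     "c.787G>A", "p.(Val263Ile)", "Missense",
                     ("Arrhythmia", "Apnea"), 0.0000121, None, 0.97394,
                     "PM1, PM2, PP3", 3),
    ReferenceVariant("a", "case_04", "3 months", "RYR2", "NM_001035.2",
                     "c.1939C>T", "p.(Arg647Cys)", "Missense",
                     ("Sudden cardiac death",), 0.0001465, "rs202040519",
                     0.96504, "PM2, PP3", 3),
    ReferenceVariant("a", "case_04", "3 months", "SCN8A", "NM_014191.3",
                     "c.5392G>A", "p.(Asp1798Asn)", "Missense",
                     ("Status epilepticus",), None, None, 0.92015,
                     "PM2, PP2", 3),
    ReferenceVariant("a", "case_05", "9 months", "AKAP9", "NM_005751.4",
                     "c.7096A>G", "p.(Ile2366Val)", "Missense",
                     ("Sudden cardiac death",), 0.0000248, "rs368823780",
                     0.08032, "PM2, BP4", 3),
    ReferenceVariant("a", "case_06", "5 weeks", "SCN5A", "NM_198056.2",
                     "c.3520C>T", "p.(Arg1174Trp)", "Missense",
                     ("Arrhythmia", "Sudden cardiac death"), 0.0000348,
                     "rs367906630", 0.9016, "PM2, PP2, PP3", 3),
    ReferenceVariant("a", "case_07", "28 years", "DTNA", "NM_001390.4",
                     "c.1571G>A", "p.(Arg524His)", "Missense",
                     ("Sudden cardiac death",), 0.0000906, "rs142108185",
                     0.50319, "PP3, BS2", 3),
    ReferenceVariant("a", "case_08", "32 years", "RAF1", "NM_002880.3",
                     "c.1334T>G", "p.(Leu445Arg)", "Missense",
                     ("Arrhythmia",), 0.0000239, None, 0.95649,
                     "PM1, PP2, PP3, BS2", 3),
    ReferenceVariant("a", "case_09", "23 years", "SCN5A", "NM_198056.2",
                     "c.3152T>C", "p.(Val1051Ala)", "Missense",
                     ("Arrhythmia", "Sudden cardiac death"), 0.000004, None,
                     0.83793, "PM2", 3),
    ReferenceVariant("a", "case_09", "23 years", "RBM20", "NM_001134363.2",
                     "c.215A>T", "p.(Asn72Ile)", "Missense",
                     ("Sudden cardiac death",), None, None, 0.80363,
                     "PM2", 3),
    ReferenceVariant("b", "case_10", "12 weeks", "CTNNA3", "NM_013266.3",
                     "c.935C>T", "p.(Ala312Val)", "Missense",
                     (), 0.0000283, None, 0.62663, "PM2", 3),
    ReferenceVariant("b", "case_03", "4 weeks", "KCNA5", "NM_002234.3",
                     "c.98A>T", "p.(Glu33Val)", "Missense",
                     (), 0.0002093, "rs71584818", 0.93829, "PM2, PP3", 3),
]


def reference_variants(part: str | None = None) -> list[ReferenceVariant]:
    """The 13 transcribed candidate variants (11 part "a", 2 part "b")."""
    if part is None:
        return list(_ROWS)
    return [r for r in _ROWS if r.part == part]


def _parse_age(age: str) -> tuple[float, str]:
    value, unit = age.split()
    return float(value), unit


def reference_cohort() -> list[CaseProfile]:
    """The 16 cohort cases: 9 adults (23-53 y) and 7 infants (4 wk - 9 mo).

    Cases case_01..case_10 carry the candidate variants above; the six
    remaining adults have synthetic representative ages (no published
    values) spaced inside the stated range.
    """
    seeds = frozenset(SEED_TERM_BY_NAME.values())
    cases: dict[str, CaseProfile] = {}
    for row in _ROWS:
        if row.case_id in cases:
            continue
        value, unit = _parse_age(row.age)
        cases[row.case_id] = CaseProfile(
            case_id=row.case_id, age_value=value, age_unit=unit, hpo_terms=seeds
        )
    for i, years in enumerate((25, 30, 35, 40, 45, 50), start=11):
        cases[f"case_{i}"] = CaseProfile(
            case_id=f"case_{i}", age_value=float(years), age_unit="years",
            hpo_terms=seeds,
        )
    return list(cases.values())


def reference_prioritized() -> dict[str, list[PrioritizedVariant]]:
    """The reference series as per-case prioritized-variant lists.

    ACMG classes are recomputed from the transcribed criteria strings via
    the combining engine (they agree with the published classes; asserted
    in tests).  Part "b" rows are marked rescued (no exact seed match).
    """
    per_case: dict[str, list[PrioritizedVariant]] = {}
    for i, row in enumerate(_ROWS):
        record = VariantRecord(
            chrom="1",
            pos=1000 + i,
            ref="A",
            alt="G",
            genotype=row.genotype,
            gene=row.gene,
            consequence=row.consequence,
            gnomad_af=row.gnomad_af,
            insilico_rank=row.metalr_rank,
            hgvs_c=row.hgvs_c,
            acmg_criteria=row.acmg_criteria,
        )
        pv = PrioritizedVariant(
            record=record,
            hpo_matches=row.hpo_match_ids,
            simscore=None,
            rescued=row.part == "b",
            moi_verdict="consistent" if row.genotype == HOM_ALT else "unknown",
            acmg=combine_criteria(parse_criteria(row.acmg_criteria)),
        )
        per_case.setdefault(row.case_id, []).append(pv)
    return per_case
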