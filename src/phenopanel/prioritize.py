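"""Second filter block: panel intersection, MOI filtering, ranking, reporting.

After the first (phenotype-agnostic) filter block, surviving variants are
intersected with the virtual gene panel, annotated with the seed phenotype
terms they match, optionally rescued by phenotype-similarity ranking,
checked for mode-of-inheritance consistency with the proband's genotype
(no parental data: compound heterozygosity is flagged, never asserted),
classified on the ACMG 5-tier scale, and deterministically ranked.
Cohort-level summaries and fixed-panel comparisons mirror the reporting a
molecular-autopsy study would print.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .acmg import ACMGClassification, combine_criteria, parse_criteria
from .ontology import GeneAnnotationSet, VirtualPanel, annotation_coverage
from .similarity import GeneSimilarityRanking, rescue_candidates
from .variant_filter import (
    HET,
    HEMI,
    HOM_ALT,
    FilterConfig,
    FunnelReport,
    VariantRecord,
    run_first_filter_block,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CaseProfile",
    "MOICatalog",
    "PrioritizedVariant",
    "CohortSummary",
    "ComparisonReport",
    "intersect_panel",
    "annotate_hpo_match",
    "filter_mode_of_inheritance",
    "rank_candidates",
    "flag_age_compatibility",
    "summarize_cohort",
    "compare_panels",
    "prioritize_case",
    "report_frame",
]

AD = "autosomal_dominant"
AR = "autosomal_recessive"
XL = "x_linked"

_UNIT_YEARS = {"years": 1.0, "year": 1.0, "months": 1 / 12, "month": 1 / 12,
               "weeks": 1 / 52.1775, "week": 1 / 52.1775}

#: Age separating the infant and adult strata of the cohort.
INFANT_ADULT_BOUNDARY_YEARS = 1.0


@dataclass(frozen=True)
class CaseProfile:
    """One decedent: identifier, age at death, assigned phenotype terms."""

    case_id: str
    age_value: float
    age_unit: str
    hpo_terms: frozenset[str]
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.age_unit not in _UNIT_YEARS:
            raise ValueError(f"unknown age unit {self.age_unit!r}")
        if not self.hpo_terms:
            raise ValueError("a case profile needs at least one phenotype term")

    @property
    def age_years(self) -> float:
        return self.age_value * _UNIT_YEARS[self.age_unit]

    @property
    def age_class(self) -> str:
        return "infant" if self.age_years < INFANT_ADULT_BOUNDARY_YEARS else "adult"


class MOICatalog:
    """Gene -> mode-of-inheritance models; absent genes are unknown-MOI."""

    def __init__(self, modes: Mapping[str, Iterable[str]]):
        self._modes = {g: frozenset(m) for g, m in modes.items()}
        self._lower = {g.lower(): g for g in self._modes}
        valid = {AD, AR, XL}
        for g, ms in self._modes.items():
            bad = ms - valid
            if bad:
                raise ValueError(f"unknown inheritance mode(s) {sorted(bad)} for {g}")

    @classmethod
    def from_tsv(cls, stream: IO[str] | str) -> "MOICatalog":
        df = pd.read_csv(stream, sep="\t", dtype=str)
        if not {"gene", "modes"} <= set(df.columns):
            raise ValueError("MOI catalog needs 'gene' and 'modes' columns")
        return cls(
            {
                row["gene"]: row["modes"].split(",")
                for _, row in df.iterrows()
                if isinstance(row["modes"], str)
            }
        )

    def modes_for(self, gene: str | None) -> frozenset[str] | None:
        if gene is None:
            return None
        sym = self._lower.get(gene.lower())
        return self._modes[sym] if sym else None

    def context_for(self, gene: str | None) -> str:
        """Frequency-filter context: dominant / recessive / unknown."""
        modes = self.modes_for(gene)
        if modes is None:
            return "unknown"
        if AD in modes or XL in modes:
            return "dominant"
        return "recessive" if AR in modes else "unknown"

    def frequency_context(self) -> dict[str, str]:
        return {g: self.context_for(g) for g in self._modes}

    def __contains__(self, gene: str) -> bool:
        return gene.lower() in self._lower


@dataclass(frozen=True)
class PrioritizedVariant:
    """A variant surviving the funnel, with phenotype and ACMG evidence."""

    record: VariantRecord
    hpo_matches: frozenset[str]
    acmg: ACMGClassification
    moi_verdict: str = "unknown"
    simscore: float | None = None
    rescued: bool = False
    age_flag: str = "unassessed"
    rank: int | None = None


def intersect_panel(
    records: Iterable[VariantRecord], panel: VirtualPanel
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Partition records by (case-insensitive) gene membership in the panel.

    Records without a gene symbol go out-of-panel with reason ``no_gene``.
    """
    in_panel, out = [], []
    for r in records:
        if r.gene is None:
            out.append((r, "no_gene"))
        elif r.gene in panel:
            in_panel.append(r)
        else:
            out.append((r, "not_in_panel"))
    return in_panel, out


def annotate_hpo_match(
    variant: VariantRecord, panel: VirtualPanel
) -> frozenset[str]:
    """The seed terms under which the variant's gene entered the panel."""
    if variant.gene is None or variant.gene not in panel:
        raise ValueError(
            f"variant {variant.key} is not in a panel gene; cannot annotate"
        )
    return panel.seeds_for_gene(variant.gene)


def filter_mode_of_inheritance(
    records: Sequence[VariantRecord], catalog: MOICatalog
) -> dict[VariantRecord, str]:
    """Per-record MOI verdict for a single proband (no parental phase).

    het in a dominant-capable gene -> consistent; hom_alt (or hemizygous in
    an X-linked gene) in a matching gene -> consistent; >= 2 distinct het
    records in a recessive-only gene -> possible_compound_het (phase
    unknowable); a single het in a recessive-only gene -> inconsistent;
    genes absent from the catalog -> unknown (retained downstream).
    """
    het_per_gene = Counter(
        r.gene.lower() for r in records if r.gene and r.genotype == HET
    )
    verdicts: dict[VariantRecord, str] = {}
    for r in records:
        modes = catalog.modes_for(r.gene)
        if modes is None:
            verdicts[r] = "unknown"
            continue
        if r.genotype == HOM_ALT:
            verdicts[r] = "consistent" if modes & {AR, AD, XL} else "unknown"
        elif r.genotype == HEMI:
            verdicts[r] = "consistent" if XL in modes or AD in modes else "inconsistent"
        else:  # het
            if AD in modes or XL in modes:
                verdicts[r] = "consistent"
            elif AR in modes:
                if r.gene and het_per_gene[r.gene.lower()] >= 2:
                    verdicts[r] = "possible_compound_het"
                else:
                    verdicts[r] = "inconsistent"
            else:
                verdicts[r] = "unknown"
    return verdicts


_MOI_ORDER = {"consistent": 0, "possible_compound_het": 1, "unknown": 2,
              "inconsistent": 3}


def rank_candidates(
    variants: Iterable[PrioritizedVariant],
) -> list[PrioritizedVariant]:
    """Deterministically order candidates and assign 1-based ranks.

    Sort priority: ACMG tier (descending), MOI verdict (consistent >
    possible compound het > unknown), number of exact seed matches,
    similarity score, then genomic position.  MOI-inconsistent variants
    sort last regardless of tier.
    """

    def key(v: PrioritizedVariant):
        return (
            v.moi_verdict == "inconsistent",
            -v.acmg.tier,
            _MOI_ORDER.get(v.moi_verdict, 2),
            -len(v.hpo_matches),
            -(v.simscore if v.simscore is not None else float("-inf")),
            v.record.chrom,
            v.record.pos,
            v.record.alt,
        )

    ordered = sorted(variants, key=key)
    return [replace(v, rank=i + 1) for i, v in enumerate(ordered)]


def flag_age_compatibility(
    variant: PrioritizedVariant,
    case: CaseProfile,
    onset_map: Mapping[str, str] | None = None,
) -> str:
    """Advisory flag: does the case's age fit the gene's typical onset?

    *onset_map* maps gene symbol -> typical onset class ("infant"/"adult").
    Returns ``unassessed`` for genes not in the map; ``atypical`` when the
    case's age class conflicts; never removes a variant.
    """
    gene = variant.record.gene
    if not onset_map or gene is None:
        return "unassessed"
    onset = {g.lower(): v for g, v in onset_map.items()}.get(gene.lower())
    if onset is None:
        return "unassessed"
    return "compatible" if onset == case.age_class else "atypical"


def prioritize_case(
    records: Sequence[VariantRecord],
    panel: VirtualPanel,
    case: CaseProfile,
    config: FilterConfig | None = None,
    moi_catalog: MOICatalog | None = None,
    ranking: GeneSimilarityRanking | None = None,
    rescue_cutoff: float = 0.01,
    onset_map: Mapping[str, str] | None = None,
) -> tuple[list[PrioritizedVariant], FunnelReport]:
    """Run the full funnel for one case and return ranked candidates.

    Stages: first filter block (quality/frequency/consequence/benign) ->
    panel intersection (+ similarity rescue of out-of-panel genes when a
    ranking is supplied) -> mode-of-inheritance filter (inconsistent
    variants dropped) -> ACMG classification from each record's criteria
    string -> deterministic ranking.  The funnel report reconciles at
    every stage.
    """
    config = config or FilterConfig()
    moi_catalog = moi_catalog or MOICatalog({})
    context = moi_catalog.frequency_context()

    kept, report = run_first_filter_block(records, config, context)

    in_panel, out = intersect_panel(kept, panel)
    rescued_records: list[VariantRecord] = []
    if ranking is not None:
        out_records = [r for r, _ in out]
        rescued_records = rescue_candidates(
            ranking, out_records, panel, percentile_cutoff=rescue_cutoff
        )
    n_dropped_panel = len(out) - len(rescued_records)
    report.record(
        "after_panel",
        len(in_panel) + len(rescued_records),
        Counter({"not_in_panel": n_dropped_panel}) if n_dropped_panel else Counter(),
    )

    stage = in_panel + rescued_records
    verdicts = filter_mode_of_inheritance(stage, moi_catalog)
    moi_kept = [r for r in stage if verdicts[r] != "inconsistent"]
    n_moi_dropped = len(stage) - len(moi_kept)
    report.record(
        "after_moi",
        len(moi_kept),
        Counter({"moi_inconsistent": n_moi_dropped}) if n_moi_dropped else Counter(),
    )

    rescued_set = set(rescued_records)
    candidates = []
    for r in moi_kept:
        rescued = r in rescued_set
        matches = frozenset() if rescued else annotate_hpo_match(r, panel)
        simscore = None
        if ranking is not None and r.gene is not None:
            lower = {g.lower(): g for g in ranking.scores}
            sym = lower.get(r.gene.lower())
            simscore = ranking.scores[sym] if sym else None
        acmg = combine_criteria(parse_criteria(r.acmg_criteria or ""))
        pv = PrioritizedVariant(
            record=r,
            hpo_matches=matches,
            acmg=acmg,
            moi_verdict=verdicts[r],
            simscore=simscore,
            rescued=rescued,
        )
        pv = replace(pv, age_flag=flag_age_compatibility(pv, case, onset_map))
        candidates.append(pv)

    ranked = rank_candidates(candidates)
    report.record("candidates", len(ranked))
    return ranked, report


@dataclass
class CohortSummary:
    """Cohort-level tallies over per-case candidate lists."""

    total_candidates: int = 0
    matches_per_seed: Counter = field(default_factory=Counter)
    per_type: Counter = field(default_factory=Counter)
    tier_tallies: Counter = field(default_factory=Counter)
    infants_with_candidate: int = 0
    adults_with_candidate: int = 0
    n_infants: int = 0
    n_adults: int = 0
    mean_candidates_per_case: float = 0.0


def _variant_type(consequence: str | None) -> str:
    if consequence is None:
        return "other"
    c = consequence.lower()
    if c == "missense_variant":
        return "missense"
    if c.startswith("splice_"):
        return "splice"
    return "other"


def summarize_cohort(
    per_case: Mapping[str, Sequence[PrioritizedVariant]],
    cases: Sequence[CaseProfile],
) -> CohortSummary:
    """Tally candidates per seed term, variant type, tier, and age stratum."""
    summary = CohortSummary()
    by_id = {c.case_id: c for c in cases}
    summary.n_infants = sum(1 for c in cases if c.age_class == "infant")
    summary.n_adults = sum(1 for c in cases if c.age_class == "adult")

    cases_with = {"infant": set(), "adult": set()}
    n_cases = max(len(cases), 1)
    for case_id, variants in per_case.items():
        for v in variants:
            summary.total_candidates += 1
            for seed in v.hpo_matches:
                summary.matches_per_seed[seed] += 1
            summary.per_type[_variant_type(v.record.consequence)] += 1
            summary.tier_tallies[v.acmg.tier] += 1
        if variants and case_id in by_id:
            cases_with[by_id[case_id].age_class].add(case_id)
    summary.infants_with_candidate = len(cases_with["infant"])
    summary.adults_with_candidate = len(cases_with["adult"])
    summary.mean_candidates_per_case = summary.total_candidates / n_cases
    return summary


@dataclass
class ComparisonReport:
    """Virtual-panel vs fixed-panel candidate comparison."""

    both: set[str]
    virtual_only: set[str]
    fixed_only: set[str]
    uncovered_fixed_genes: set[str]

    @property
    def union_size(self) -> int:
        return len(self.both | self.virtual_only | self.fixed_only)


def compare_panels(
    virtual_candidates: Iterable[PrioritizedVariant],
    fixed_candidates: Iterable[PrioritizedVariant],
    fixed_panel_genes: Iterable[str],
    annotations: GeneAnnotationSet | None = None,
) -> ComparisonReport:
    """Compare candidate variant sets found by each panel approach.

    Candidates are matched by variant key.  When an annotation set is
    supplied, fixed-panel genes lacking any direct phenotype annotation
    are listed (they can never enter a phenotype-driven panel).
    """
    v_keys = {v.record.key for v in virtual_candidates}
    f_keys = {v.record.key for v in fixed_candidates}
    genes = list(fixed_panel_genes)
    uncovered = (
        annotation_coverage(genes, annotations) if annotations and genes else set()
    )
    return ComparisonReport(
        both=v_keys & f_keys,
        virtual_only=v_keys - f_keys,
        fixed_only=f_keys - v_keys,
        uncovered_fixed_genes=uncovered,
    )


_REPORT_COLUMNS = [
    "case_id", "age", "rank", "gene", "hgvs_c", "variant_type", "hpo_match",
    "gnomad_af", "insilico_rank", "acmg_criteria", "acmg_class",
    "moi_verdict", "simscore", "rescued", "age_flag", "chrom", "pos",
    "ref", "alt", "genotype",
]


def report_frame(
    per_case: Mapping[str, Sequence[PrioritizedVariant]],
    cases: Sequence[CaseProfile],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate report table, one row per prioritized variant."""
    by_id = {c.case_id: c for c in cases}
    rows = []
    for case_id in sorted(per_case):
        case = by_id.get(case_id)
        for v in per_case[case_id]:
            names = sorted(
                (term_names or {}).get(t, t) for t in v.hpo_matches
            )
            rows.append(
                {
                    "case_id": case_id,
                    "age": f"{case.age_value:g} {case.age_unit}" if case else "",
                    "rank": v.rank,
                    "gene": v.record.gene,
                    "hgvs_c": v.record.hgvs_c,
                    "variant_type": _variant_type(v.record.consequence),
                    "hpo_match": ";".join(names),
                    "gnomad_af": v.record.gnomad_af,
                    "insilico_rank": v.record.insilico_rank,
                    "acmg_criteria": v.record.acmg_criteria,
                    "acmg_class": v.acmg.tier,
                    "moi_verdict": v.moi_verdict,
                    "simscore": v.simscore,
                    "rescued": v.rescued,
                    "age_flag": v.age_flag,
                    "chrom": v.record.chrom,
                    "pos": v.record.pos,
                    "ref": v.record.ref,
                    "alt": v.record.alt,
                    "genotype": v.record.genotype,
                }
            )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
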