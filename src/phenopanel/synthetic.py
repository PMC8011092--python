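"""Synthetic ontologies, annotation sets and exome-scale variant cohorts.

Real molecular-autopsy data cannot be redistributed, so every stage of the
pipeline is exercised on simulated inputs with the statistical structure
the method assumes:

* toy phenotype ontologies (random multi-parent DAGs with known closures);
* a structured simulation scenario — a two-branch ontology whose four seed
  terms induce a known virtual panel, a gene universe split into panel and
  background genes, and a mode-of-inheritance catalog;
* per-case mini- or full-exome variant sets in which each variant is
  constructed either to survive the first filter block (with configured
  probability) or to fail it at one designated stage, so the funnel's
  empirical pass rate is exactly binomial;
* planted causal variants in panel genes with genotypes consistent (or
  deliberately inconsistent) with the gene's inheritance model, tracked in
  a ground-truth manifest for recovery testing.

All randomness flows from one integer seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import (
    GeneAnnotationSet,
    OntologyGraph,
    VirtualPanel,
    build_virtual_panel,
    parse_gene_annotations,
    parse_obo,
)
from .prioritize import AD, AR, CaseProfile, MOICatalog
from .variant_filter import HET, HOM_ALT, FilterConfig, VariantRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "GroundTruthEntry",
    "ToyOntology",
    "Scenario",
    "Cohort",
    "generate_toy_ontology",
    "build_scenario",
    "generate_case_profiles",
    "generate_sample_records",
    "generate_sample_vcf",
    "generate_cohort",
]

_QUALIFYING = (
    "missense_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "stop_gained",
    "frameshift_variant",
    "inframe_insertion",
)
_QUALIFYING_W = (0.78, 0.05, 0.05, 0.06, 0.05, 0.01)
_NON_QUALIFYING = ("synonymous_variant", "intron_variant", "3_prime_utr_variant")
_NON_QUALIFYING_W = (0.45, 0.45, 0.10)

_FAILURE_MODES = ("common_allele", "non_qualifying", "benign_label", "low_quality")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the reference study's design: 16 cases (9 adults aged
    23-53 years, 7 infants aged 4-39 weeks), a mean of 68,947 variants per
    sample, and a first-filter-block survival fraction of 0.004
    (approximately 276 of 68,947).  Among survivors, ~1.9% fall in virtual-
    panel genes; combined with the inheritance-model mix below (60%
    dominant-capable, 27.5% recessive-only, 12.5% unknown) and the small
    compound-het retention of paired hets in recessive-only genes at full
    exome scale, this calibrates the panel-plus-inheritance prioritization
    rate to the study's 4-of-276 (~1.45%) funnel proportion (derivation in
    the methods note).  Use :meth:`mini` for fast 2,000-variant
    "mini-exomes" with the same rates.
    """

    seed: int = 0
    n_adults: int = 9
    n_infants: int = 7
    variants_per_sample: int = 68_947
    first_block_pass_rate: float = 0.004
    panel_hit_rate: float = 0.0193
    p_novel_af: float = 0.15
    failure_mix: tuple[float, ...] = (0.75, 0.17, 0.05, 0.03)
    plant_causal: bool = True
    moi_scenario: str = "AR_hom"  # AD_het | AR_hom | AR_comphet | AR_single_het
    adult_age_years: tuple[int, int] = (23, 53)
    infant_age_weeks: tuple[int, int] = (4, 39)
    n_panel_genes: int = 60
    n_background_genes: int = 240
    # P(AD only), P(AD+AR), P(AR only), P(no catalog entry)
    moi_mix: tuple[float, ...] = (0.475, 0.125, 0.275, 0.125)

    def __post_init__(self) -> None:
        for p in (self.first_block_pass_rate, self.panel_hit_rate, self.p_novel_af):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for mix in (self.failure_mix, self.moi_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("categorical weights must sum to 1")
        if self.variants_per_sample <= 0:
            raise ValueError("variants_per_sample must be positive")
        if self.moi_scenario not in {"AD_het", "AR_hom", "AR_comphet", "AR_single_het"}:
            raise ValueError(f"unknown MOI scenario {self.moi_scenario!r}")

    @property
    def n_cases(self) -> int:
        return self.n_adults + self.n_infants

    def mini(self, **overrides) -> "SimulationConfig":
        """A 2,000-variant mini-exome configuration with identical rates."""
        return replace(self, variants_per_sample=2_000, **overrides)


@dataclass(frozen=True)
class GroundTruthEntry:
    """Planted-variant bookkeeping for one case."""

    case_id: str
    variant_keys: tuple[str, ...]
    gene: str
    moi_scenario: str
    expected_candidacy: bool


# ---------------------------------------------------------------------------
# Toy ontologies


@dataclass(frozen=True)
class ToyOntology:
    """A generated ontology + annotation set with their text serializations."""

    obo_text: str
    annotation_text: str
    graph: OntologyGraph
    annotations: GeneAnnotationSet


def _obo_text(stanzas: Sequence[tuple[str, str, Sequence[str]]]) -> str:
    """Serialize (id, name, parents) triples as OBO 1.2 text."""
    parts = ["format-version: 1.2", "ontology: toy", ""]
    for term_id, name, parents in stanzas:
        parts.append("[Term]")
        parts.append(f"id: {term_id}")
        parts.append(f"name: {name}")
        for p in parents:
            parts.append(f"is_a: {p} ! {name} parent")
        parts.append("")
    return "\n".join(parts)


def _annotation_text(pairs: Sequence[tuple[str, str]]) -> str:
    lines = ["gene_symbol\thpo_id"]
    lines += [f"{g}\t{t}" for g, t in pairs]
    return "\n".join(lines) + "\n"


def generate_toy_ontology(
    seed: int,
    n_terms: int = 20,
    max_parents: int = 3,
    n_genes: int = 12,
) -> ToyOntology:
    """Generate a random single-root multi-parent DAG plus annotations.

    Term i > 1 receives 1..max_parents parents drawn from earlier terms, so
    the is-a relation is acyclic by construction; every gene is annotated
    to at least one term.  Deterministic for a fixed seed, byte-level.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    ids = [f"HP:{i + 1:07d}" for i in range(n_terms)]
    stanzas: list[tuple[str, str, list[str]]] = [(ids[0], "term 1 (root)", [])]
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = sorted(
            ids[j] for j in rng.choice(i, size=k, replace=False)
        )
        stanzas.append((ids[i], f"term {i + 1}", parents))

    pairs: list[tuple[str, str]] = []
    for g in range(n_genes):
        gene = f"G{g + 1:04d}"
        k = min(int(rng.integers(1, 4)), n_terms)
        terms = sorted(ids[j] for j in rng.choice(n_terms, size=k, replace=False))
        pairs += [(gene, t) for t in terms]

    obo = _obo_text(stanzas)
    ann = _annotation_text(pairs)
    graph = parse_obo(obo)
    import io

    annotations = parse_gene_annotations(io.StringIO(ann), graph)
    return ToyOntology(obo, ann, graph, annotations)


# ---------------------------------------------------------------------------
# Simulation scenario


@dataclass(frozen=True)
class Scenario:
    """Everything a simulated cohort runs against."""

    toy: ToyOntology
    seed_terms: frozenset[str]
    panel: VirtualPanel
    moi_catalog: MOICatalog
    panel_genes: tuple[str, ...]
    background_genes: tuple[str, ...]

    @property
    def graph(self) -> OntologyGraph:
        return self.toy.graph

    @property
    def annotations(self) -> GeneAnnotationSet:
        return self.toy.annotations

    def panel_genes_with_modes(self, required: frozenset[str], exact: bool = False):
        out = []
        for g in self.panel_genes:
            modes = self.moi_catalog.modes_for(g)
            if modes is None:
                continue
            if (modes == required) if exact else (required <= modes):
                out.append(g)
        return out


def build_scenario(config: SimulationConfig) -> Scenario:
    """Build the two-branch ontology scenario the simulator samples from.

    Branch "cardiorespiratory/neurological" holds four seed terms (each
    with three child terms) annotated by the panel genes; an unrelated
    branch holds the terms annotated by background genes.  The virtual
    panel induced by the seeds therefore contains exactly the panel genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    seeds = ["HP:0011675", "HP:0001645", "HP:0002133", "HP:0002104"]
    seed_names = ["arrhythmia", "sudden cardiac death", "status epilepticus", "apnea"]
    root = "HP:0000001"
    other_branch = "HP:0000002"

    stanzas: list[tuple[str, str, list[str]]] = [
        (root, "phenotypic abnormality (root)", []),
        (other_branch, "unrelated abnormality", [root]),
    ]
    seed_children: dict[str, list[str]] = {}
    next_id = 100
    for s, name in zip(seeds, seed_names):
        stanzas.append((s, name, [root]))
        seed_children[s] = []
        for _ in range(3):
            child = f"HP:{next_id:07d}"
            next_id += 1
            stanzas.append((child, f"{name} subtype", [s]))
            seed_children[s].append(child)
    other_terms = []
    for _ in range(12):
        t = f"HP:{next_id:07d}"
        next_id += 1
        stanzas.append((t, "unrelated subtype", [other_branch]))
        other_terms.append(t)

    panel_terms = [t for s in seeds for t in [s] + seed_children[s]]
    pairs: list[tuple[str, str]] = []
    panel_genes = tuple(f"PANEL{i + 1:04d}" for i in range(config.n_panel_genes))
    background = tuple(f"BG{i + 1:04d}" for i in range(config.n_background_genes))
    for g in panel_genes:
        k = int(rng.integers(1, 3))
        terms = sorted(
            panel_terms[j] for j in rng.choice(len(panel_terms), k, replace=False)
        )
        pairs += [(g, t) for t in terms]
    for g in background:
        k = int(rng.integers(1, 3))
        terms = sorted(
            other_terms[j] for j in rng.choice(len(other_terms), k, replace=False)
        )
        pairs += [(g, t) for t in terms]

    obo = _obo_text(stanzas)
    ann = _annotation_text(pairs)
    graph = parse_obo(obo)
    import io

    annotations = parse_gene_annotations(io.StringIO(ann), graph)
    panel = build_virtual_panel(graph, annotations, seeds)
    toy = ToyOntology(obo, ann, graph, annotations)

    mode_sets = (frozenset({AD}), frozenset({AD, AR}), frozenset({AR}), None)
    modes: dict[str, frozenset[str]] = {}
    all_genes = panel_genes + background
    draws = rng.choice(4, size=len(all_genes), p=config.moi_mix)
    for g, d in zip(all_genes, draws):
        if mode_sets[d] is not None:
            modes[g] = mode_sets[d]
    # the simulator must always be able to plant each scenario
    ar_only = [g for g in panel_genes if modes.get(g) == frozenset({AR})]
    ad_capable = [g for g in panel_genes if modes.get(g) and AD in modes[g]]
    if not ar_only:
        modes[panel_genes[0]] = frozenset({AR})
    if not ad_capable:
        modes[panel_genes[1]] = frozenset({AD})

    return Scenario(
        toy=toy,
        seed_terms=frozenset(seeds),
        panel=panel,
        moi_catalog=MOICatalog(modes),
        panel_genes=panel_genes,
        background_genes=background,
    )


def generate_case_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> list[CaseProfile]:
    """Case table: adults uniform in years, infants uniform in weeks."""
    seeds = frozenset({"HP:0011675", "HP:0001645", "HP:0002133", "HP:0002104"})
    cases = []
    lo, hi = config.adult_age_years
    for i in range(config.n_adults):
        cases.append(
            CaseProfile(
                case_id=f"sim_adult_{i + 1:02d}",
                age_value=float(rng.integers(lo, hi + 1)),
                age_unit="years",
                hpo_terms=seeds,
            )
        )
    lo, hi = config.infant_age_weeks
    for i in range(config.n_infants):
        cases.append(
            CaseProfile(
                case_id=f"sim_infant_{i + 1:02d}",
                age_value=float(rng.integers(lo, hi + 1)),
                age_unit="weeks",
                hpo_terms=seeds,
            )
        )
    return cases


def _plant_records(
    config: SimulationConfig,
    scenario: Scenario,
    case: CaseProfile,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], GroundTruthEntry]:
    """Construct the planted causal variant(s) for one case."""
    fc = FilterConfig()
    scen = config.moi_scenario
    if scen in ("AR_hom", "AR_comphet", "AR_single_het"):
        pool = scenario.panel_genes_with_modes(frozenset({AR}), exact=True)
    else:
        pool = [
            g
            for g in scenario.panel_genes
            if (m := scenario.moi_catalog.modes_for(g)) and AD in m
        ]
    if not pool:
        raise ValueError(
            f"cannot plant {scen}: no panel gene with the required "
            "inheritance model in the MOI catalog"
        )
    gene = pool[int(rng.integers(len(pool)))]
    base_pos = 90_000_000 + int(rng.integers(0, 1_000_000)) * 4

    def rec(offset: int, genotype: str, af, consequence: str, criteria: str):
        return VariantRecord(
            chrom="1",
            pos=base_pos + offset,
            ref="G",
            alt="A",
            genotype=genotype,
            depth=80,
            genotype_quality=99,
            gene=gene,
            consequence=consequence,
            gnomad_af=af,
            acmg_criteria=criteria,
        )

    if scen == "AR_hom":
        # AF between the dominant and recessive cutoffs: survives only via
        # the homozygous/recessive relaxation of the frequency filter.
        af = float(rng.uniform(fc.max_af_dominant * 1.2, fc.max_af_recessive * 0.95))
        records = [rec(0, HOM_ALT, af, "splice_acceptor_variant", "PVS1, PM2")]
        expected = True
    elif scen == "AD_het":
        records = [rec(0, HET, None, "splice_donor_variant", "PVS1, PM2")]
        expected = True
    elif scen == "AR_comphet":
        records = [
            rec(0, HET, None, "splice_acceptor_variant", "PVS1, PM2"),
            rec(2, HET, float(rng.uniform(0, fc.max_af_dominant * 0.9)),
                "missense_variant", "PM2, PP3"),
        ]
        expected = True
    else:  # AR_single_het: inconsistent with recessive inheritance
        records = [rec(0, HET, None, "missense_variant", "PM2")]
        expected = False
    return records, GroundTruthEntry(
        case_id=case.case_id,
        variant_keys=tuple(r.key for r in records),
        gene=gene,
        moi_scenario=scen,
        expected_candidacy=expected,
    )


def generate_sample_records(
    config: SimulationConfig,
    scenario: Scenario,
    case: CaseProfile,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], GroundTruthEntry | None]:
    """One sample's variant set; survival of the first block is binomial.

    Each background variant is constructed either to pass the whole first
    filter block (probability ``first_block_pass_rate``) or to fail exactly
    one designated stage, with the failure stage drawn from ``failure_mix``
    (common allele / non-qualifying consequence / benign label / low
    quality).  Planted records are appended per the MOI scenario.
    """
    fc = FilterConfig()
    n = int(rng.poisson(config.variants_per_sample))
    positions = np.cumsum(rng.integers(1, 600, size=n))
    survives = rng.random(n) < config.first_block_pass_rate
    failure = rng.choice(4, size=n, p=config.failure_mix)
    u_gene = rng.random(n)
    gene_idx_panel = rng.integers(0, len(scenario.panel_genes), size=n)
    gene_idx_bg = rng.integers(0, len(scenario.background_genes), size=n)
    u_af = rng.random(n)
    af_novel = rng.random(n) < config.p_novel_af
    csq_pass = rng.choice(len(_QUALIFYING), size=n, p=_QUALIFYING_W)
    csq_fail = rng.choice(len(_NON_QUALIFYING), size=n, p=_NON_QUALIFYING_W)
    depth = rng.integers(30, 120, size=n)
    gq = rng.integers(60, 100, size=n)
    low_depth = rng.integers(0, fc.min_depth, size=n)
    pm2 = rng.random(n) < 0.9
    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)

    records: list[VariantRecord] = []
    for i in range(n):
        if u_gene[i] < config.panel_hit_rate:
            gene = scenario.panel_genes[gene_idx_panel[i]]
        else:
            gene = scenario.background_genes[gene_idx_bg[i]]
        ref = bases[ref_idx[i]]
        alt = bases[(ref_idx[i] + alt_shift[i]) % 4]
        common = dict(
            chrom="1",
            pos=int(positions[i]),
            ref=str(ref),
            alt=str(alt),
            genotype=HET,
            gene=gene,
        )
        if survives[i]:
            af = None if af_novel[i] else float(u_af[i] * fc.max_af_dominant * 0.98)
            records.append(
                VariantRecord(
                    depth=int(depth[i]),
                    genotype_quality=int(gq[i]),
                    consequence=_QUALIFYING[csq_pass[i]],
                    gnomad_af=af,
                    acmg_criteria="PM2" if pm2[i] else None,
                    **common,
                )
            )
            continue
        mode = _FAILURE_MODES[failure[i]]
        if mode == "common_allele":
            records.append(
                VariantRecord(
                    depth=int(depth[i]),
                    genotype_quality=int(gq[i]),
                    consequence=_QUALIFYING[csq_pass[i]],
                    gnomad_af=float(0.01 + u_af[i] * 0.49),
                    **common,
                )
            )
        elif mode == "non_qualifying":
            af = None if af_novel[i] else float(u_af[i] * fc.max_af_dominant * 0.98)
            records.append(
                VariantRecord(
                    depth=int(depth[i]),
                    genotype_quality=int(gq[i]),
                    consequence=_NON_QUALIFYING[csq_fail[i]],
                    gnomad_af=af,
                    **common,
                )
            )
        elif mode == "benign_label":
            records.append(
                VariantRecord(
                    depth=int(depth[i]),
                    genotype_quality=int(gq[i]),
                    consequence=_QUALIFYING[csq_pass[i]],
                    gnomad_af=float(u_af[i] * fc.max_af_dominant * 0.98),
                    clinvar_sig="Likely_benign" if u_af[i] < 0.5 else "Benign",
                    **common,
                )
            )
        else:  # low_quality
            records.append(
                VariantRecord(
                    depth=int(low_depth[i]),
                    genotype_quality=int(gq[i]),
                    consequence=_QUALIFYING[csq_pass[i]],
                    gnomad_af=None if af_novel[i] else float(u_af[i] * fc.max_af_dominant),
                    **common,
                )
            )

    truth = None
    if config.plant_causal:
        planted, truth = _plant_records(config, scenario, case, rng)
        records.extend(planted)
    return records, truth


def generate_sample_vcf(
    config: SimulationConfig,
    scenario: Scenario,
    case: CaseProfile,
    path: str,
    rng: np.random.Generator,
) -> GroundTruthEntry | None:
    """Generate one sample and write it as a single-sample VCF v4.2."""
    records, truth = generate_sample_records(config, scenario, case, rng)
    write_vcf(records, path, sample=case.case_id)
    return truth


@dataclass
class Cohort:
    """A simulated cohort: scenario, cases, per-case records, ground truth."""

    config: SimulationConfig
    scenario: Scenario
    cases: list[CaseProfile]
    records_by_case: dict[str, list[VariantRecord]]
    ground_truth: list[GroundTruthEntry] = field(default_factory=list)


def generate_cohort(
    config: SimulationConfig, outdir: str | None = None
) -> Cohort:
    """Generate the full cohort; optionally write it to *outdir*.

    When *outdir* is given, writes one VCF per case plus ``cases.tsv``,
    ``ground_truth.tsv``, ``ontology.obo``, ``annotations.tsv``,
    ``panel.tsv`` and ``moi_catalog.tsv``.
    """
    scenario = build_scenario(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    cases = generate_case_profiles(config, rng)
    records_by_case: dict[str, list[VariantRecord]] = {}
    truths: list[GroundTruthEntry] = []
    for case in cases:
        records, truth = generate_sample_records(config, scenario, case, rng)
        records_by_case[case.case_id] = records
        if truth is not None:
            truths.append(truth)

    cohort = Cohort(config, scenario, cases, records_by_case, truths)
    if outdir is not None:
        _write_cohort(cohort, outdir)
    return cohort


def _write_cohort(cohort: Cohort, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for case in cohort.cases:
        write_vcf(
            cohort.records_by_case[case.case_id],
            os.path.join(outdir, f"{case.case_id}.vcf"),
            sample=case.case_id,
        )
    pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "age_value": c.age_value,
                "age_unit": c.age_unit,
                "age_class": c.age_class,
                "hpo_terms": ";".join(sorted(c.hpo_terms)),
            }
            for c in cohort.cases
        ]
    ).to_csv(os.path.join(outdir, "cases.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "case_id": t.case_id,
                "variant_keys": ";".join(t.variant_keys),
                "gene": t.gene,
                "moi_scenario": t.moi_scenario,
                "expected_candidacy": t.expected_candidacy,
            }
            for t in cohort.ground_truth
        ],
        columns=["case_id", "variant_keys", "gene", "moi_scenario", "expected_candidacy"],
    ).to_csv(os.path.join(outdir, "ground_truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "ontology.obo"), "wt", newline="\n") as fh:
        fh.write(cohort.scenario.toy.obo_text)
    with open(os.path.join(outdir, "annotations.tsv"), "wt", newline="\n") as fh:
        fh.write(cohort.scenario.toy.annotation_text)
    cohort.scenario.panel.to_frame(cohort.scenario.graph).to_csv(
        os.path.join(outdir, "panel.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"gene": g, "modes": ",".join(sorted(m))}
            for g, m in sorted(cohort.scenario.moi_catalog._modes.items())
        ]
    ).to_csv(os.path.join(outdir, "moi_catalog.tsv"), sep="\t", index=False)
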