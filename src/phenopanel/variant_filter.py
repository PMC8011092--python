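"""Annotated-VCF reading and the first block of the variant filter funnel.

Exome-scale molecular-autopsy analysis starts from tens of thousands of
called variants per sample.  The first filter block reduces them by

    quality -> population frequency -> functional impact -> known-benign

before any phenotype-driven step.  Each stage partitions its input into
kept and removed records (one removal reason per record), and a funnel
report tracks per-stage counts so runs reconcile exactly.

VCF reading is backed by :mod:`cyvcf2`; annotations are taken from INFO
keys (configurable dialect) or an optional sidecar TSV keyed by
``chrom:pos:ref:alt``.  Missing annotations stay missing — an absent
population frequency is never coerced to zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VcfParseError",
    "SidecarFormatError",
    "VariantRecord",
    "FilterConfig",
    "AnnotationDialect",
    "FunnelReport",
    "read_annotated_vcf",
    "write_vcf",
    "filter_quality",
    "filter_frequency",
    "filter_consequence",
    "exclude_known_benign",
    "run_first_filter_block",
    "DEFAULT_KEPT_CONSEQUENCES",
    "DEFAULT_BENIGN_LABELS",
]

HET = "het"
HOM_ALT = "hom_alt"
HEMI = "hemi"
_GENOTYPES = frozenset({HET, HOM_ALT, HEMI})

#: Functional-impact classes retained by default: missense, stop, frameshift,
#: splice-site variants and in-frame insertions.
DEFAULT_KEPT_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "inframe_insertion",
    }
)

#: Database classifications treated as benign/likely benign (5-tier classes
#: 1 and 2 included as plain strings).
DEFAULT_BENIGN_LABELS = frozenset(
    {"benign", "likely_benign", "benign/likely_benign", "1", "2"}
)


class VcfParseError(ValueError):
    """A VCF could not be parsed; carries a line number where possible."""


class SidecarFormatError(ValueError):
    """The sidecar annotation TSV is malformed (e.g. duplicate keys)."""


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One annotated variant call (one ALT allele of one VCF record)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    depth: int | None = None
    genotype_quality: int | None = None
    gene: str | None = None
    consequence: str | None = None
    gnomad_af: float | None = None
    clinvar_sig: str | None = None
    lovd_class: str | None = None
    insilico_rank: float | None = None
    hgvs_c: str | None = None
    acmg_criteria: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the first filter block.

    The source study published no numeric cutoffs; these defaults are
    inferred so that every reported candidate variant passes (max dominant
    context AF observed 1.465e-4; the retained homozygous recessive variant
    sits at 1.7889e-3).  All are overridable.
    """

    min_depth: int = 20
    min_genotype_quality: int = 20
    max_af_dominant: float = 5e-4
    max_af_recessive: float = 2e-3
    kept_consequences: frozenset[str] = DEFAULT_KEPT_CONSEQUENCES
    benign_labels: frozenset[str] = DEFAULT_BENIGN_LABELS
    drop_unknown_consequence: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_genotype_quality < 0:
            raise ValueError("quality thresholds must be nonnegative")
        if self.max_af_dominant > self.max_af_recessive:
            raise ValueError("max_af_dominant must be <= max_af_recessive")


@dataclass(frozen=True)
class AnnotationDialect:
    """Names of the INFO keys carrying variant annotations."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    gnomad_af: str = "GNOMAD_AF"
    clinvar: str = "CLNSIG"
    lovd: str = "LOVD_CLASS"
    insilico: str = "METALR"
    hgvs_c: str = "HGVSC"
    acmg_criteria: str = "ACMG_CRIT"


DEFAULT_DIALECT = AnnotationDialect()

_FUNNEL_STAGES = (
    "input",
    "after_quality",
    "after_frequency",
    "after_consequence",
    "after_benign_exclusion",
    "after_panel",
    "after_moi",
    "candidates",
)


@dataclass
class FunnelReport:
    """Per-stage survivor counts and removal-reason tallies."""

    counts: dict[str, int] = field(default_factory=dict)
    removals: dict[str, Counter] = field(default_factory=dict)

    STAGES = _FUNNEL_STAGES

    def record(self, stage: str, n_kept: int, reasons: Counter | None = None):
        self.counts[stage] = n_kept
        if reasons is not None:
            self.removals[stage] = Counter(reasons)

    def reconciles(self) -> bool:
        """Counts non-increasing and removals account for every drop."""
        seq = [self.counts[s] for s in _FUNNEL_STAGES if s in self.counts]
        if any(b > a for a, b in zip(seq, seq[1:])):
            return False
        prev = None
        for stage in _FUNNEL_STAGES:
            if stage not in self.counts:
                continue
            if prev is not None and stage in self.removals:
                if prev - self.counts[stage] != sum(self.removals[stage].values()):
                    return False
            prev = self.counts[stage]
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, "kept": self.counts[s]}
            for s in _FUNNEL_STAGES
            if s in self.counts
        ]
        return pd.DataFrame(rows, columns=["stage", "kept"])


# ---------------------------------------------------------------------------
# VCF I/O


def _classify_genotype(gt_alleles: Sequence[int], alt_index: int) -> str | None:
    called = [a for a in gt_alleles if a >= 0]
    if not called:
        return HET  # uncalled genotype: record the allele, assume carrier
    copies = sum(1 for a in called if a == alt_index)
    if len(called) == 1:
        return HEMI if copies == 1 else None
    if copies == 2:
        return HOM_ALT
    if copies == 1:
        return HET
    return None


def _structural_check(path: str) -> None:
    """Cheap line-level validation so parse errors carry line numbers."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: malformed VCF line {lineno}: "
                    f"expected >= 8 tab-separated fields, got {len(fields)}"
                )
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"{path}: malformed VCF line {lineno}: POS is not an integer"
                )


def _info_scalar(value, alt_index: int):
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    return value


def read_annotated_vcf(
    path: str,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
    sidecar: str | None = None,
) -> list[VariantRecord]:
    """Read a single-sample annotated VCF into :class:`VariantRecord` list.

    Multi-allelic sites are split into one record per ALT allele carried by
    the genotype; symbolic ALTs (CNV-style ``<DEL>`` etc.) are skipped with
    a logged ``unsupported_cnv`` count.  Missing annotations stay ``None``.
    An optional sidecar TSV (columns ``chrom, pos, ref, alt`` plus any
    annotation columns) overrides/fills INFO annotations; duplicate sidecar
    keys raise :class:`SidecarFormatError`.
    """
    from cyvcf2 import VCF

    _structural_check(path)
    side = _load_sidecar(sidecar) if sidecar else {}

    records: list[VariantRecord] = []
    skipped = Counter()
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib-level failure
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    for v in vcf:
        gts = v.genotypes[0][:-1] if v.genotypes else []
        for i, alt in enumerate(v.ALT):
            if alt.startswith("<"):
                skipped["unsupported_cnv"] += 1
                continue
            genotype = _classify_genotype(gts, i + 1)
            if genotype is None:
                skipped["alt_not_in_genotype"] += 1
                continue
            depth = _format_int(v, "DP")
            gq = _format_int(v, "GQ")

            def info(key):
                return _info_scalar(v.INFO.get(key), i)

            fields = {
                "gene": _opt_str(info(dialect.gene)),
                "consequence": _opt_str(info(dialect.consequence)),
                "gnomad_af": _opt_float(info(dialect.gnomad_af)),
                "clinvar_sig": _opt_str(info(dialect.clinvar)),
                "lovd_class": _opt_str(info(dialect.lovd)),
                "insilico_rank": _opt_float(info(dialect.insilico)),
                "hgvs_c": _opt_str(info(dialect.hgvs_c)),
                "acmg_criteria": _opt_str(info(dialect.acmg_criteria)),
            }
            key = f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            if key in side:
                for k, val in side[key].items():
                    if k in fields and val is not None:
                        fields[k] = val
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    genotype=genotype,
                    depth=depth,
                    genotype_quality=gq,
                    **fields,
                )
            )
    if skipped:
        logger.info("skipped records while reading %s: %s", path, dict(skipped))
    return records


def _format_int(v, key: str) -> int | None:
    try:
        arr = v.format(key)
    except KeyError:
        arr = None
    if arr is None:
        val = v.INFO.get(key)
        return int(val) if val is not None else None
    val = int(arr[0][0]) if arr.ndim == 2 else int(arr[0])
    return val if val >= 0 else None


def _opt_str(v) -> str | None:
    if v is None:
        return None
    # undo VCF percent-encoding applied by write_vcf
    s = str(v).strip()
    for code, ch in (("%3B", ";"), ("%3D", "="), ("%2C", ","), ("%20", " "), ("%25", "%")):
        s = s.replace(code, ch)
    return s


def _opt_float(v) -> float | None:
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


_SIDECAR_FIELDS = {
    "gene": _opt_str,
    "consequence": _opt_str,
    "gnomad_af": _opt_float,
    "clinvar_sig": _opt_str,
    "lovd_class": _opt_str,
    "insilico_rank": _opt_float,
    "hgvs_c": _opt_str,
    "acmg_criteria": _opt_str,
}


def _load_sidecar(path: str) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise SidecarFormatError(
            f"sidecar {path} lacks key columns {sorted(required)}"
        )
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        if key in out:
            raise SidecarFormatError(f"sidecar {path}: duplicate key {key}")
        out[key] = {
            col: conv(row[col])
            for col, conv in _SIDECAR_FIELDS.items()
            if col in df.columns and isinstance(row[col], str)
        }
    return out


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence (Sequence Ontology)">
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD allele frequency">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar classification">
##INFO=<ID=LOVD_CLASS,Number=1,Type=String,Description="LOVD classification">
##INFO=<ID=METALR,Number=1,Type=Float,Description="MetaLR rank score">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="Coding HGVS">
##INFO=<ID=ACMG_CRIT,Number=1,Type=String,Description="ACMG criteria string">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_GT_STRINGS = {HET: "0/1", HOM_ALT: "1/1", HEMI: "1"}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    sample: str = "SAMPLE",
    contig: str = "1",
    contig_length: int = 250_000_000,
) -> None:
    """Write records as a minimal single-sample VCF v4.2 text file.

    INFO encoding is the default :class:`AnnotationDialect`; spaces and
    semicolons in string annotations are percent-encoded per VCF rules.
    Records are written in (chrom, pos, alt) order for determinism.
    """

    def enc(s: str) -> str:
        return (
            s.replace("%", "%25")
            .replace(";", "%3B")
            .replace("=", "%3D")
            .replace(",", "%2C")
            .replace(" ", "%20")
        )

    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(
            _VCF_HEADER.format(contig=contig, length=contig_length, sample=sample)
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = []
            if r.gene is not None:
                info.append(f"GENE={enc(r.gene)}")
            if r.consequence is not None:
                info.append(f"CSQ={enc(r.consequence)}")
            if r.gnomad_af is not None:
                info.append(f"GNOMAD_AF={r.gnomad_af:.10g}")
            if r.clinvar_sig is not None:
                info.append(f"CLNSIG={enc(r.clinvar_sig)}")
            if r.lovd_class is not None:
                info.append(f"LOVD_CLASS={enc(r.lovd_class)}")
            if r.insilico_rank is not None:
                info.append(f"METALR={r.insilico_rank:.10g}")
            if r.hgvs_c is not None:
                info.append(f"HGVSC={enc(r.hgvs_c)}")
            if r.acmg_criteria is not None:
                info.append(f"ACMG_CRIT={enc(r.acmg_criteria)}")
            fmt_vals = [_GT_STRINGS[r.genotype]]
            fmt_keys = ["GT"]
            if r.depth is not None:
                fmt_keys.append("DP")
                fmt_vals.append(str(r.depth))
            if r.genotype_quality is not None:
                fmt_keys.append("GQ")
                fmt_vals.append(str(r.genotype_quality))
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        ".",
                        r.ref,
                        r.alt,
                        ".",
                        "PASS",
                        ";".join(info) or ".",
                        ":".join(fmt_keys),
                        ":".join(fmt_vals),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filters

Removed = list[tuple[VariantRecord, str]]


def filter_quality(
    records: Iterable[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], Removed]:
    """Keep records with depth and genotype quality at/above thresholds.

    Records lacking a depth or GQ annotation are retained (missing metric
    is unknown, not failing).
    """
    kept, removed = [], []
    for r in records:
        if r.depth is not None and r.depth < config.min_depth:
            removed.append((r, "low_depth"))
        elif (
            r.genotype_quality is not None
            and r.genotype_quality < config.min_genotype_quality
        ):
            removed.append((r, "low_genotype_quality"))
        else:
            kept.append(r)
    return kept, removed


def filter_frequency(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    moi_context: Mapping[str, str] | None = None,
    het_counts: Mapping[str, int] | None = None,
) -> tuple[list[VariantRecord], Removed]:
    """Population-frequency filter with a recessive-context relaxation.

    A record passes when its gnomAD AF is absent (never observed) or at or
    below the dominant cutoff.  Records between the dominant and recessive
    cutoffs survive only in a recessive gene context when the genotype is
    homozygous or the gene carries >= 2 het hits (potential compound
    heterozygote).  *het_counts* (lower-cased gene -> het record count)
    should be computed on the whole sample so the predicate is per-record;
    it defaults to counting within *records*.
    """
    records = list(records)
    moi_context = moi_context or {}
    context_lower = {g.lower(): c for g, c in moi_context.items()}
    het_hits = (
        Counter(het_counts)
        if het_counts is not None
        else Counter(r.gene.lower() for r in records if r.gene and r.genotype == HET)
    )
    kept, removed = [], []
    for r in records:
        af = r.gnomad_af
        if af is None or af <= config.max_af_dominant:
            kept.append(r)
            continue
        gene = r.gene.lower() if r.gene else None
        recessive = gene is not None and context_lower.get(gene) == "recessive"
        if (
            af <= config.max_af_recessive
            and recessive
            and (r.genotype == HOM_ALT or het_hits[gene] >= 2)
        ):
            kept.append(r)
        else:
            removed.append((r, "common_allele"))
    return kept, removed


def filter_consequence(
    records: Iterable[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], Removed]:
    """Keep records whose consequence is in the qualifying set.

    Consequence terms are compared case-insensitively.  Records with no
    consequence annotation, or one outside the Sequence Ontology terms seen
    in config, are removed as ``unknown_consequence`` unless
    ``drop_unknown_consequence`` is disabled.
    """
    known = {c.lower() for c in config.kept_consequences} | {
        "synonymous_variant",
        "intron_variant",
        "intergenic_variant",
        "5_prime_utr_variant",
        "3_prime_utr_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "inframe_deletion",
        "start_lost",
        "splice_region_variant",
        "non_coding_transcript_variant",
    }
    kept_lower = {c.lower() for c in config.kept_consequences}
    kept, removed = [], []
    for r in records:
        csq = r.consequence.lower() if r.consequence else None
        if csq in kept_lower:
            kept.append(r)
        elif csq is None or csq not in known:
            if config.drop_unknown_consequence:
                logger.warning("unknown consequence term %r removed", csq)
                removed.append((r, "unknown_consequence"))
            else:
                kept.append(r)
        else:
            removed.append((r, "non_qualifying_consequence"))
    return kept, removed


def _normalize_label(label: str) -> str:
    out = label.strip().lower()
    for ch in " -":
        out = out.replace(ch, "_")
    while "__" in out:
        out = out.replace("__", "_")
    return out


def exclude_known_benign(
    records: Iterable[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], Removed]:
    """Discard records a variant database classifies benign/likely benign.

    Labels are normalized (case, spaces/hyphens) before exact matching;
    'conflicting interpretations of pathogenicity' never matches.
    """
    benign = {_normalize_label(b) for b in config.benign_labels}
    kept, removed = [], []
    for r in records:
        labels = [x for x in (r.clinvar_sig, r.lovd_class) if x is not None]
        if any(_normalize_label(x) in benign for x in labels):
            removed.append((r, "known_benign"))
        else:
            kept.append(r)
    return kept, removed


def run_first_filter_block(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    moi_context: Mapping[str, str] | None = None,
    report: FunnelReport | None = None,
) -> tuple[list[VariantRecord], FunnelReport]:
    """Quality -> frequency -> consequence -> benign exclusion, with counts."""
    records = list(records)
    report = report if report is not None else FunnelReport()
    report.record("input", len(records))
    # compound-het support is judged on the whole sample, not on whatever
    # subset survived an earlier stage
    het_counts = Counter(
        r.gene.lower() for r in records if r.gene and r.genotype == HET
    )

    kept, removed = filter_quality(records, config)
    report.record("after_quality", len(kept), Counter(r for _, r in removed))

    kept, removed = filter_frequency(kept, config, moi_context, het_counts)
    report.record("after_frequency", len(kept), Counter(r for _, r in removed))

    kept, removed = filter_consequence(kept, config)
    report.record("after_consequence", len(kept), Counter(r for _, r in removed))

    kept, removed = exclude_known_benign(kept, config)
    report.record(
        "after_benign_exclusion", len(kept), Counter(r for _, r in removed)
    )
    return kept, report
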