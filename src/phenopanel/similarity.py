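"""Information-content semantic similarity between phenotype term sets.

Commercial analysis platforms ship proprietary phenotype-similarity scores
that rank genes by how well their phenotype annotations match a case's
terms, rescuing candidate genes that do not fall inside the virtual panel.
This module implements the standard, well-characterized analog: Resnik term
similarity (information content of the most informative common ancestor,
MICA) combined by symmetric best-match average (BMA) over term sets.  It is
documented as a "simscore (Resnik-BMA analog)" and makes no claim of
numeric equivalence with any proprietary score.

Information content of a term t is ``-ln(n_t / N)`` where ``n_t`` counts
genes whose ancestor-propagated annotations contain t and N is the number
of annotated genes; rarer terms are more informative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ontology import GeneAnnotationSet, OntologyGraph, VirtualPanel

logger = logging.getLogger(__name__)

__all__ = [
    "InformationContentTable",
    "GeneSimilarityRanking",
    "compute_information_content",
    "term_similarity",
    "set_similarity",
    "rank_genes_by_similarity",
    "rescue_candidates",
    "DEFAULT_RESCUE_PERCENTILE_CUTOFF",
]

#: Fraction of top-ranked genes eligible for rescue ("highest range" of the
#: gene ranking).
DEFAULT_RESCUE_PERCENTILE_CUTOFF = 0.01


@dataclass(frozen=True)
class InformationContentTable:
    """Per-term information content; terms never annotated are absent."""

    ic: Mapping[str, float]
    n_genes: int

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def compute_information_content(
    annotations: GeneAnnotationSet,
) -> InformationContentTable:
    """IC(t) = -ln(n_t / N) over ancestor-propagated annotations."""
    n = annotations.gene_universe_size
    if n < 1:
        raise ValueError("annotation set contains no genes")
    counts: dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log(c / n) for t, c in counts.items()}
    return InformationContentTable(ic=ic, n_genes=n)


def term_similarity(
    graph: OntologyGraph,
    ic_table: InformationContentTable,
    t1: str,
    t2: str,
) -> float:
    """Resnik similarity: max IC over the common ancestor-or-self set."""
    a = {graph.resolve(t1)} | graph.ancestors(t1)
    b = {graph.resolve(t2)} | graph.ancestors(t2)
    common = a & b
    return max((ic_table.get(t, 0.0) for t in common), default=0.0)


def set_similarity(
    graph: OntologyGraph,
    ic_table: InformationContentTable,
    case_terms: Iterable[str],
    gene_terms: Iterable[str],
) -> float:
    """Symmetric best-match-average similarity between two term sets."""
    case = list(dict.fromkeys(case_terms))
    gene = list(dict.fromkeys(gene_terms))
    if not case or not gene:
        raise ValueError("set_similarity requires two nonempty term sets")
    sim = {
        (a, b): term_similarity(graph, ic_table, a, b) for a in case for b in gene
    }
    fwd = sum(max(sim[(a, b)] for b in gene) for a in case) / len(case)
    rev = sum(max(sim[(a, b)] for a in case) for b in gene) / len(gene)
    return (fwd + rev) / 2.0


@dataclass(frozen=True)
class GeneSimilarityRanking:
    """Gene scores with dense ranks (ties share a rank) and percentiles.

    ``percentile[g]`` is the fraction of genes with strictly lower score,
    so the best genes sit near 1.
    """

    scores: Mapping[str, float]
    ranks: Mapping[str, int]
    percentile: Mapping[str, float]

    def to_frame(self):
        import pandas as pd

        rows = sorted(
            self.scores, key=lambda g: (self.ranks[g], g)
        )
        return pd.DataFrame(
            {
                "gene": rows,
                "score": [self.scores[g] for g in rows],
                "rank": [self.ranks[g] for g in rows],
                "percentile": [self.percentile[g] for g in rows],
            }
        )


def rank_genes_by_similarity(
    graph: OntologyGraph,
    ic_table: InformationContentTable,
    annotations: GeneAnnotationSet,
    case_terms: Iterable[str],
) -> GeneSimilarityRanking:
    """Score every annotated gene against the case's term set.

    Genes are scored via :func:`set_similarity` against their DIRECT term
    sets; ranks are dense (rank 1 = best, ties share a rank) with
    lexicographic gene-symbol tie-breaks applied only to output ordering.
    """
    case = [graph.resolve(t) for t in case_terms]
    if not case:
        raise ValueError("case term set must be nonempty")
    scores = {
        gene: set_similarity(graph, ic_table, case, terms)
        for gene, terms in annotations.direct.items()
    }
    distinct = sorted(set(scores.values()), reverse=True)
    rank_of = {s: i + 1 for i, s in enumerate(distinct)}
    ranks = {g: rank_of[s] for g, s in scores.items()}
    n = len(scores)
    below = {s: sum(1 for v in scores.values() if v < s) for s in distinct}
    percentile = {g: below[s] / n for g, s in scores.items()}
    return GeneSimilarityRanking(scores=scores, ranks=ranks, percentile=percentile)


def rescue_candidates(
    ranking: GeneSimilarityRanking,
    variants: Sequence,
    panel: VirtualPanel,
    percentile_cutoff: float = DEFAULT_RESCUE_PERCENTILE_CUTOFF,
) -> list:
    """Flag out-of-panel variants whose gene ranks in the top score range.

    A variant is rescued when its gene is NOT in the panel and the gene's
    score percentile is at least ``1 - percentile_cutoff``.  Panel variants
    are never rescued; variants in genes absent from the ranking are
    skipped with a logged reason.
    """
    if not (0.0 < percentile_cutoff <= 1.0):
        raise ValueError("percentile_cutoff must lie in (0, 1]")
    threshold = 1.0 - percentile_cutoff
    rescued = []
    lower = {g.lower(): g for g in ranking.scores}
    for v in variants:
        gene = getattr(v, "gene", None)
        if gene is None or gene in panel:
            continue
        sym = lower.get(gene.lower())
        if sym is None:
            logger.info("gene %s absent from similarity ranking; skipped", gene)
            continue
        if ranking.percentile[sym] >= threshold:
            rescued.append(v)
    return rescued
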