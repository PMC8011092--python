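"""Phenotype-ontology handling and virtual gene panel construction.

The Human Phenotype Ontology (HPO) and similar vocabularies are directed
acyclic graphs of terms linked by is-a (subclass) edges; a specialized term
may have several less specialized parents.  Genes are annotated to terms,
and by the true-path rule a gene annotated to a term is implicitly annotated
to every ancestor of that term.  A *virtual gene panel* is the gene set
induced by a handful of clinically chosen seed terms: every gene whose
direct annotations intersect a seed term or any of its descendants.

This module parses an OBO 1.2 subset (via :mod:`obonet`), validates the
graph structure, computes ancestor/descendant closures, propagates gene
annotations, and builds virtual panels with per-gene provenance.
"""

from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OntologyStructureError",
    "TermLookupError",
    "AnnotationFormatError",
    "OntologyTerm",
    "OntologyGraph",
    "GeneAnnotationSet",
    "AnnotationParseReport",
    "VirtualPanel",
    "parse_obo",
    "ancestors",
    "descendants",
    "parse_gene_annotations",
    "build_virtual_panel",
    "annotation_coverage",
    "DEFAULT_SEED_TERMS",
]

#: Seed terms used for sudden-unexplained-death casework: arrhythmia,
#: sudden cardiac death, status epilepticus, apnea.
DEFAULT_SEED_TERMS = frozenset(
    {"HP:0011675", "HP:0001645", "HP:0002133", "HP:0002104"}
)

_TERM_ID_RE = re.compile(r"^[A-Za-z]+:\d+$")


class OntologyError(ValueError):
    """Base class for ontology-related failures."""


class OntologyStructureError(OntologyError):
    """The ontology violates a structural invariant (cycle, dangling edge...)."""


class TermLookupError(KeyError):
    """A term accession (primary or alternative) is not in the graph."""


class AnnotationFormatError(ValueError):
    """The gene-phenotype annotation table cannot be interpreted."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: accession, label, is-a parents, alt ids, obsolescence."""

    term_id: str
    name: str
    parent_ids: frozenset[str] = frozenset()
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _TERM_ID_RE.match(self.term_id):
            raise OntologyError(f"malformed term accession: {self.term_id!r}")


class OntologyGraph:
    """An is-a DAG of ontology terms with alt-id and obsolescence handling.

    Obsolete terms are kept (flagged) but excluded from traversal.  Alt ids
    are transparent: any lookup by an alt id behaves exactly as a lookup by
    the primary id it maps to.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise OntologyStructureError(
                    f"duplicate primary id: {term.term_id}"
                )
            self.terms[term.term_id] = term

        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.terms:
                    raise OntologyStructureError(
                        f"alt_id {alt} collides with a primary id"
                    )
                if alt in self._alt:
                    raise OntologyStructureError(
                        f"alt_id {alt} maps to both {self._alt[alt]} "
                        f"and {term.term_id}"
                    )
                self._alt[alt] = term.term_id

        # child -> parent digraph over non-obsolete terms only
        self._dag = nx.DiGraph()
        for term in self.terms.values():
            if term.obsolete:
                continue
            self._dag.add_node(term.term_id)
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise OntologyStructureError(
                        f"term {term.term_id} lists unknown parent {parent}"
                    )
                if self.terms[parent].obsolete:
                    raise OntologyStructureError(
                        f"term {term.term_id} lists obsolete parent {parent}"
                    )
                self._dag.add_edge(term.term_id, parent)

        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise OntologyStructureError(
                f"is-a relation is cyclic; cycle involves {cycle[0][0]}"
            )

        self.root_ids: frozenset[str] = frozenset(
            n for n in self._dag.nodes if self._dag.out_degree(n) == 0
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def resolve(self, term_id: str) -> str:
        """Map a primary or alternative accession to its primary accession."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise TermLookupError(f"unknown term accession: {term_id}")

    def term(self, term_id: str) -> OntologyTerm:
        return self.terms[self.resolve(term_id)]

    def name(self, term_id: str) -> str:
        return self.term(term_id).name

    def ancestors(self, term_id: str) -> set[str]:
        """All proper ancestors (self excluded) over every is-a path."""
        primary = self.resolve(term_id)
        if primary not in self._dag:
            return set()  # obsolete terms do not traverse
        return set(nx.descendants(self._dag, primary))

    def descendants(self, term_id: str) -> set[str]:
        """All proper descendants (self excluded); dual of :meth:`ancestors`."""
        primary = self.resolve(term_id)
        if primary not in self._dag:
            return set()
        return set(nx.ancestors(self._dag, primary))


def parse_obo(stream: IO[str] | str) -> OntologyGraph:
    """Parse an OBO 1.2 subset into a validated :class:`OntologyGraph`.

    Recognized stanza tags: ``id``, ``name``, ``is_a`` (with trailing
    ``! comment`` stripping), ``alt_id``, ``is_obsolete``.  Other tags and
    non-is-a relationships are ignored (counted in the log).  Structural
    errors — cyclic is-a, dangling parent ids, duplicate primary ids —
    raise :class:`OntologyStructureError`.

    Parameters
    ----------
    stream:
        An open text stream, OBO text, or a filesystem path.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
        if "[Term]" not in text:  # treat as a path
            with open(text, "rt", encoding="utf-8") as fh:
                text = fh.read()

    # obonet silently merges duplicate stanzas; detect them first.
    ids = [
        line.split(":", 1)[1].strip().split(" !")[0].strip()
        for line in _stanza_id_lines(text)
    ]
    dupes = [i for i, n in Counter(ids).items() if n > 1]
    if dupes:
        raise OntologyStructureError(f"duplicate primary id: {dupes[0]}")

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    n_other_relations = sum(
        1 for _, _, key in graph.edges(keys=True) if key != "is_a"
    )
    if n_other_relations:
        logger.info(
            "ignoring %d non-is-a relationship edge(s)", n_other_relations
        )

    terms: list[OntologyTerm] = []
    for node, data in graph.nodes(data=True):
        if "name" not in data and "is_a" not in data and not graph.in_edges(node):
            # node exists only because another stanza referenced it
            raise OntologyStructureError(
                f"dangling parent id: {node} is referenced but never defined"
            )
        if "name" not in data:
            raise OntologyStructureError(
                f"dangling parent id: {node} is referenced but never defined"
            )
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data["name"],
                parent_ids=parents,
                alt_ids=frozenset(data.get("alt_id", [])),
                obsolete=obsolete,
            )
        )
    return OntologyGraph(terms)


def _stanza_id_lines(text: str) -> list[str]:
    out, in_term = [], False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            out.append(line)
            in_term = False  # only the first id line of a stanza
    return out


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Proper ancestors of *term_id* (self excluded), over all is-a paths."""
    return graph.ancestors(term_id)


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """Proper descendants of *term_id* (self excluded)."""
    return graph.descendants(term_id)


@dataclass
class AnnotationParseReport:
    """Bookkeeping for rows dropped while reading an annotation table."""

    total_rows: int = 0
    skipped_rows: int = 0
    reasons: Counter = field(default_factory=Counter)


class GeneAnnotationSet:
    """Direct and ancestor-propagated gene-to-term annotations.

    Gene symbols are stored case-preserved and matched case-insensitively
    (annotation files and VCF annotations disagree on case in the wild).
    """

    def __init__(
        self,
        direct: Mapping[str, Iterable[str]],
        graph: OntologyGraph,
        parse_report: AnnotationParseReport | None = None,
    ):
        self.direct: dict[str, frozenset[str]] = {
            g: frozenset(graph.resolve(t) for t in ts) for g, ts in direct.items()
        }
        self.propagated: dict[str, frozenset[str]] = {}
        for gene, terms in self.direct.items():
            closure: set[str] = set(terms)
            for t in terms:
                closure |= graph.ancestors(t)
            self.propagated[gene] = frozenset(closure)
        self._by_lower = {g.lower(): g for g in self.direct}
        self.parse_report = parse_report or AnnotationParseReport(
            total_rows=sum(len(v) for v in self.direct.values())
        )

    @property
    def gene_universe_size(self) -> int:
        return len(self.direct)

    @property
    def genes(self) -> set[str]:
        return set(self.direct)

    def canonical_symbol(self, gene: str) -> str | None:
        return self._by_lower.get(gene.lower())

    def __contains__(self, gene: str) -> bool:
        return gene.lower() in self._by_lower

    def direct_terms(self, gene: str) -> frozenset[str]:
        sym = self.canonical_symbol(gene)
        return self.direct[sym] if sym else frozenset()

    def propagated_terms(self, gene: str) -> frozenset[str]:
        sym = self.canonical_symbol(gene)
        return self.propagated[sym] if sym else frozenset()


def parse_gene_annotations(
    stream: IO[str] | str,
    graph: OntologyGraph,
    gene_column: str = "gene_symbol",
    term_column: str = "hpo_id",
) -> GeneAnnotationSet:
    """Read a genes-to-phenotype style TSV into a :class:`GeneAnnotationSet`.

    The table must carry a header naming at least *gene_column* and
    *term_column*; extra columns are tolerated.  Alt ids resolve to primary
    ids; rows citing unknown or obsolete terms are skipped and counted in
    ``parse_report``.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, comment=None)
    if df.empty and df.columns.size == 0:
        raise AnnotationFormatError("annotation table is empty")
    missing = {gene_column, term_column} - set(df.columns)
    if missing:
        raise AnnotationFormatError(
            f"annotation table lacks required column(s): {sorted(missing)}"
        )
    if df.empty:
        raise AnnotationFormatError("annotation table has a header but no rows")

    report = AnnotationParseReport(total_rows=len(df))
    direct: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_column], df[term_column]):
        if not isinstance(gene, str) or not isinstance(term, str):
            report.skipped_rows += 1
            report.reasons["blank_field"] += 1
            continue
        term = term.strip()
        try:
            primary = graph.resolve(term)
        except TermLookupError:
            report.skipped_rows += 1
            report.reasons["unknown_term"] += 1
            continue
        if graph.terms[primary].obsolete:
            report.skipped_rows += 1
            report.reasons["obsolete_term"] += 1
            continue
        direct.setdefault(gene.strip(), set()).add(primary)
    if report.skipped_rows:
        logger.warning(
            "skipped %d/%d annotation rows (%s)",
            report.skipped_rows,
            report.total_rows,
            dict(report.reasons),
        )
    return GeneAnnotationSet(direct, graph, parse_report=report)


@dataclass(frozen=True)
class VirtualPanel:
    """A gene panel induced by seed phenotype terms, with provenance.

    ``provenance[gene]`` is the set of ``(seed_term, matched_term)`` pairs:
    the gene is in the panel because one of its direct annotations
    (*matched_term*) is the seed term itself or one of its descendants.
    """

    seed_terms: frozenset[str]
    genes: frozenset[str]
    provenance: Mapping[str, frozenset[tuple[str, str]]]

    def __contains__(self, gene: str) -> bool:
        return gene.lower() in self._genes_lower

    @property
    def _genes_lower(self) -> frozenset[str]:
        return frozenset(g.lower() for g in self.genes)

    def seeds_for_gene(self, gene: str) -> frozenset[str]:
        """Seed terms under which *gene* entered the panel."""
        for g, pairs in self.provenance.items():
            if g.lower() == gene.lower():
                return frozenset(seed for seed, _ in pairs)
        return frozenset()

    def to_frame(self, graph: OntologyGraph | None = None) -> pd.DataFrame:
        """Panel as a deterministic table: one row per provenance pair."""
        rows = []
        for gene in sorted(self.genes):
            for seed, matched in sorted(self.provenance[gene]):
                rows.append(
                    {
                        "gene": gene,
                        "seed_term": seed,
                        "matched_term": matched,
                        "matched_term_name": graph.name(matched) if graph else "",
                    }
                )
        return pd.DataFrame(
            rows, columns=["gene", "seed_term", "matched_term", "matched_term_name"]
        )


def build_virtual_panel(
    graph: OntologyGraph,
    annotations: GeneAnnotationSet,
    seed_terms: Iterable[str],
) -> VirtualPanel:
    """Build the virtual panel induced by *seed_terms*.

    A gene enters the panel iff one of its DIRECT annotations lies in a
    seed term's descendant closure (seed included) — equivalently, iff its
    propagated annotations contain the seed itself.
    """
    seeds = [graph.resolve(s) for s in seed_terms]
    if not seeds:
        raise ValueError("seed term set must be nonempty")

    closures = {s: {s} | graph.descendants(s) for s in seeds}
    provenance: dict[str, frozenset[tuple[str, str]]] = {}
    for gene, terms in annotations.direct.items():
        pairs = {
            (seed, t)
            for seed, closure in closures.items()
            for t in terms
            if t in closure
        }
        if pairs:
            provenance[gene] = frozenset(pairs)
    return VirtualPanel(
        seed_terms=frozenset(seeds),
        genes=frozenset(provenance),
        provenance=provenance,
    )


def annotation_coverage(
    gene_list: Iterable[str], annotations: GeneAnnotationSet
) -> set[str]:
    """Return the genes in *gene_list* that carry no direct annotation."""
    genes = list(gene_list)
    if not genes:
        logger.warning("annotation_coverage called with an empty gene list")
        return set()
    return {g for g in genes if g not in annotations}
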