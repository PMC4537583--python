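"""Resnik GO semantic similarity (GOSS).

Information content of a term is IC(t) = −ln(n_t / N), where n_t counts genes
annotated to t or any descendant (true-path propagation) and N is the number
of genes with at least one annotation in the namespace.  The Resnik similarity
of two terms is the IC of their most informative common ancestor: high when
the deepest shared term is specific (few genes), zero when the terms share
only the namespace root.  Gene-pair GOSS is the maximum Resnik similarity over
all pairs of the two genes' annotated terms.

Annotations with a NOT qualifier or ND (No biological Data available) evidence
are removed on load.  Only ``is_a`` edges are traversed by default;
``part_of`` can be enabled.  IC uses the natural logarithm by default (so a
GOSS of 6 means the shared ancestor covers < e^-6 ≈ 0.25 % of the corpus);
the base is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationSet",
    "load_obo",
    "load_gaf",
    "propagate_annotations",
    "information_content",
    "resnik_term",
    "goss_gene",
    "GossScorer",
]

_NAMESPACE_CODE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_ASPECT_TO_CODE = {"P": "BP", "F": "MF", "C": "CC"}


@dataclass
class GoDag:
    """Ontology structure: term → parent sets over ``is_a`` (and optionally
    ``part_of``) edges, with per-namespace roots."""

    parents: dict[str, set[str]]
    namespace: dict[str, str]  # term -> BP / MF / CC
    roots: dict[str, str] = field(default_factory=dict)  # namespace -> root term

    def __post_init__(self) -> None:
        g = nx.DiGraph((c, p) for c, ps in self.parents.items() for p in ps)
        g.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        if not self.roots:
            for term, ps in self.parents.items():
                if not ps:
                    self.roots[self.namespace[term]] = term
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including itself."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        acc = {term}
        for p in self.parents[term]:
            acc |= self.ancestors(p)
        result = frozenset(acc)
        self._anc_cache[term] = result
        return result


@dataclass
class AnnotationSet:
    """Direct gene → GO-term annotations, already ND/NOT-filtered."""

    direct: dict[str, set[str]]  # gene -> directly annotated terms

    def genes(self) -> list[str]:
        return sorted(self.direct)

    def terms_of(self, gene: str, dag: GoDag | None = None, namespace: str | None = None) -> set[str]:
        terms = self.direct.get(gene, set())
        if namespace is not None:
            if dag is None:
                raise ValueError("namespace filtering requires the DAG")
            terms = {t for t in terms if dag.namespace.get(t) == namespace}
        return terms

    def corpus_size(self, dag: GoDag, namespace: str) -> int:
        return sum(1 for g in self.direct if self.terms_of(g, dag, namespace))


def load_obo(path: str | Path, include_part_of: bool = False) -> GoDag:
    """Parse an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are dropped (obonet excludes them).  Edges kept are
    ``is_a`` and, if requested, ``part_of`` relationships.
    """
    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        namespace[term] = _NAMESPACE_CODE.get(ns, ns)
        parents[term] = set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" or (include_part_of and key == "part_of"):
            if parent in parents:
                parents[child].add(parent)
    return GoDag(parents=parents, namespace=namespace)


def load_gaf(path: str | Path, dag: GoDag) -> AnnotationSet:
    """Parse a GAF 2.x annotation file against ``dag``.

    Rows with a NOT qualifier or ND evidence are dropped; rows annotating a
    term absent from the ontology are skipped with a warning.  Genes are keyed
    by DB object symbol when present, else DB object id.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if any(q.upper().startswith("NOT") for q in rec["Qualifier"] if q):
                continue
            if rec["Evidence"] == "ND":
                continue
            term = rec["GO_ID"]
            gene = rec["DB_Object_Symbol"] or rec["DB_Object_ID"]
            if term not in dag.terms:
                logger.warning("skipping annotation %s -> %s: term not in ontology", gene, term)
                continue
            direct.setdefault(gene, set()).add(term)
    return AnnotationSet(direct=direct)


def propagate_annotations(dag: GoDag, ann: AnnotationSet) -> dict[str, set[str]]:
    """True-path propagation: term → set of genes annotated to it or below.

    Every gene annotated anywhere in a namespace is counted at that
    namespace's root.
    """
    term_genes: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in ann.direct.items():
        for t in terms:
            for anc in dag.ancestors(t):
                term_genes[anc].add(gene)
    return term_genes


def information_content(
    dag: GoDag,
    ann: AnnotationSet,
    namespace: str = "BP",
    log_base: float | None = None,
) -> dict[str, float]:
    """IC table for one namespace: term → −log(n_t / N).

    ``log_base=None`` means natural log.  Terms with zero propagated count are
    omitted (IC undefined).  The namespace root always has IC 0.
    """
    term_genes = propagate_annotations(dag, ann)
    n_total = ann.corpus_size(dag, namespace)
    if n_total == 0:
        return {}
    scale = 1.0 if log_base is None else math.log(log_base)
    ic = {}
    for term, genes in term_genes.items():
        if dag.namespace.get(term) != namespace or not genes:
            continue
        ic[term] = -math.log(len(genes) / n_total) / scale
    return ic


def resnik_term(t1: str, t2: str, ic: dict[str, float], dag: GoDag) -> float:
    """Resnik similarity: IC of the most informative common ancestor."""
    if dag.namespace.get(t1) != dag.namespace.get(t2):
        raise ValueError(f"cross-namespace comparison: {t1} vs {t2}")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    values = [ic[t] for t in common if t in ic]
    if not values:
        return 0.0
    return max(values)


def goss_gene(
    g1: str,
    g2: str,
    ann: AnnotationSet,
    ic: dict[str, float],
    dag: GoDag,
    namespace: str = "BP",
) -> float:
    """Gene-pair GOSS: maximum Resnik similarity over the genes' annotations.

    Equivalently (and computed as) the maximum IC over terms that are
    ancestors of at least one annotation of each gene.  Raises ``KeyError``
    if either gene has no annotation in the namespace.
    """
    t1 = ann.terms_of(g1, dag, namespace)
    t2 = ann.terms_of(g2, dag, namespace)
    if not t1:
        raise KeyError(f"gene {g1} has no {namespace} annotations")
    if not t2:
        raise KeyError(f"gene {g2} has no {namespace} annotations")
    anc1: set[str] = set().union(*(dag.ancestors(t) for t in t1))
    anc2: set[str] = set().union(*(dag.ancestors(t) for t in t2))
    values = [ic[t] for t in anc1 & anc2 if t in ic]
    return max(values) if values else 0.0


class GossScorer:
    """Bound gene-pair GOSS with memoisation, for use inside TAPAS loops."""

    def __init__(self, ann: AnnotationSet, ic: dict[str, float], dag: GoDag,
                 namespace: str = "BP"):
        self.ann, self.ic, self.dag, self.namespace = ann, ic, dag, namespace
        self._cache: dict[frozenset[str], float] = {}

    def has_annotation(self, gene: str) -> bool:
        return bool(self.ann.terms_of(gene, self.dag, self.namespace))

    def __call__(self, g1: str, g2: str) -> float:
        key = frozenset((g1, g2))
        if key not in self._cache:
            self._cache[key] = goss_gene(g1, g2, self.ann, self.ic, self.dag, self.namespace)
        return self._cache[key]
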