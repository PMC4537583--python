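"""TAPAS — Transcript Annotation Pipeline for Alternative Splicing.

Given a query isoform (typically a minor isoform of a High-TS gene), TAPAS
characterises its functional neighbourhood in three steps:

1. **Cluster** — collect every transcript from *other* genes whose expression
   profile has Pearson correlation above a threshold (default 0.7) with the
   query profile.
2. **Link** — record a functional link from the query gene to each member
   gene backed by an experimental protein interaction, a high-confidence
   STRING score (> 800), or a highly specific GO semantic similarity
   (GOSS > 6, biological-process branch).  Any link resolves the cluster as
   ``linked``.
3. **Fallback filter** — otherwise, take the closest *k* (default 20) member
   isoforms whose genes carry BP GO terms and compute the mean pairwise
   gene-gene GOSS among those member genes (the query's own gene excluded).
   A mean at or above the cutoff (default 2.5, far above the random
   background similarity) resolves the cluster as ``goss_pass``; otherwise it
   is ``discarded``.

The validation step compares, per cluster, the mean GOSS between member genes
and the query's parent gene across passed clusters, discarded clusters and a
size-matched random-membership control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import TimeCourseMatrix
from .goss import GossScorer
from .stats import mann_whitney_one_sided

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "TapasCluster",
    "TapasConfig",
    "build_cluster",
    "attach_links",
    "fallback_filter",
    "validate_filtering",
    "run_tapas",
    "load_ppi",
    "load_string",
]

LINKED = "linked"
GOSS_PASS = "goss_pass"
DISCARDED = "discarded"
UNRESOLVED = "unresolved"


@dataclass
class InteractionNetwork:
    """Experimental PPI edges plus STRING-style scored edges (0–1000)."""

    experimental: set[frozenset[str]] = field(default_factory=set)
    string: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.experimental:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
        for e, s in self.string.items():
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if not 0 <= s <= 1000:
                raise ValueError(f"STRING score {s} outside 0–1000")

    def experimental_link(self, g1: str, g2: str) -> bool:
        return frozenset((g1, g2)) in self.experimental

    def string_score(self, g1: str, g2: str) -> int | None:
        return self.string.get(frozenset((g1, g2)))


def load_ppi(path: str | Path) -> set[frozenset[str]]:
    """Experimental PPI edge list: ``geneA<TAB>geneB``; self-edges dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"],
                     dtype=str, comment="#")
    return {frozenset((a, b)) for a, b in zip(df["a"], df["b"]) if a != b}


def load_string(path: str | Path) -> dict[frozenset[str], int]:
    """STRING-style edge list: ``geneA<TAB>geneB<TAB>score``; best score kept."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"],
                     dtype={"a": str, "b": str}, comment="#")
    edges: dict[frozenset[str], int] = {}
    for a, b, s in zip(df["a"], df["b"], df["score"].astype(int)):
        if a == b:
            continue
        key = frozenset((a, b))
        edges[key] = max(int(s), edges.get(key, 0))
    return edges


@dataclass
class TapasConfig:
    sim_threshold: float = 0.7
    string_cutoff: int = 800
    goss_link_cutoff: float = 6.0
    fallback_k: int = 20
    fallback_mean_cutoff: float = 2.5


@dataclass
class TapasCluster:
    query_transcript_id: str
    query_gene_id: str
    # (transcript_id, gene_id, pearson similarity), similarity descending
    members: list[tuple[str, str, float]] = field(default_factory=list)
    # (member gene, link type, score)
    links: list[tuple[str, str, float]] = field(default_factory=list)
    verdict: str = UNRESOLVED
    mean_member_goss: float | None = None
    reason: str | None = None

    def member_genes(self) -> list[str]:
        """Member genes, deduplicated, in order of best member similarity."""
        seen, out = set(), []
        for _, gene, _ in self.members:
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
        return out

    def best_isoform_of(self, gene: str) -> tuple[str, float]:
        for tid, g, sim in self.members:
            if g == gene:
                return tid, sim
        raise KeyError(gene)


def _pearson_to_query(query: np.ndarray, candidates: pd.DataFrame) -> pd.Series:
    """Vectorised Pearson correlation of each candidate row with the query."""
    x = candidates.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    qc = query - query.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((qc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ qc) / denom
    return pd.Series(np.clip(r, -1.0, 1.0), index=candidates.index)


def build_cluster(
    query: str,
    m: TimeCourseMatrix,
    sim_threshold: float = 0.7,
) -> TapasCluster:
    """Collect transcripts from other genes co-expressed with the query.

    Membership requires Pearson correlation strictly above ``sim_threshold``.
    Transcripts of the query's own gene are never members; candidates with a
    constant profile are skipped with a warning.  Members are sorted by
    similarity descending, ties broken by transcript id.
    """
    qprof = m.profile(query)
    if np.ptp(qprof) == 0:
        raise ValueError(f"query {query} has a constant profile; Pearson undefined")
    qgene = m.gene_of(query)
    foreign = [t for t in m.transcript_ids if m.transcript_to_gene[t] != qgene]
    cluster = TapasCluster(query_transcript_id=query, query_gene_id=qgene)
    if not foreign:
        return cluster
    cand = m.values.loc[foreign]
    r = _pearson_to_query(qprof, cand)
    n_const = int(r.isna().sum())
    if n_const:
        logger.warning("query %s: skipped %d constant candidate profiles", query, n_const)
    hits = r.dropna()
    hits = hits[hits > sim_threshold]
    members = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    cluster.members = [(tid, m.gene_of(tid), float(sim)) for tid, sim in members]
    return cluster


def attach_links(
    c: TapasCluster,
    net: InteractionNetwork,
    goss_fn: GossScorer | None,
    string_cutoff: int = 800,
    goss_cutoff: float = 6.0,
) -> TapasCluster:
    """Record functional links between the query gene and member genes.

    A member gene is linked by an experimental PPI edge, a STRING score
    strictly above ``string_cutoff``, or a gene-pair GOSS strictly above
    ``goss_cutoff``.  The cluster verdict becomes ``linked`` if any link
    exists, else stays ``unresolved`` for the fallback filter.
    """
    links: list[tuple[str, str, float]] = []
    query_annotated = goss_fn is not None and goss_fn.has_annotation(c.query_gene_id)
    for gene in c.member_genes():
        if net.experimental_link(c.query_gene_id, gene):
            links.append((gene, "experimental", 1.0))
        score = net.string_score(c.query_gene_id, gene)
        if score is not None and score > string_cutoff:
            links.append((gene, "string", float(score)))
        if query_annotated and goss_fn.has_annotation(gene):
            g = goss_fn(c.query_gene_id, gene)
            if g > goss_cutoff:
                links.append((gene, "goss", float(g)))
    c.links = links
    c.verdict = LINKED if links else UNRESOLVED
    return c


def _mean_pairwise_goss(genes: list[str], goss_fn: GossScorer) -> float:
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    return float(np.mean([goss_fn(a, b) for a, b in pairs]))


def fallback_filter(
    c: TapasCluster,
    goss_fn: GossScorer,
    k: int = 20,
    mean_cutoff: float = 2.5,
) -> TapasCluster:
    """GOSS coherence fallback for clusters without direct functional links.

    The ``k`` most-similar members whose genes carry BP GO terms are taken
    (each foreign gene counted once, at its best-correlated isoform); the
    mean gene-gene GOSS over all unordered pairs of those member genes —
    the query's own gene is never among them — decides the verdict:
    ``goss_pass`` if mean >= ``mean_cutoff``, else ``discarded``.  Fewer than
    two annotated member genes cannot form a pair: ``discarded`` with reason
    "insufficient annotation".
    """
    if c.verdict == LINKED:
        return c
    annotated_genes: list[str] = []
    for tid, gene, _sim in c.members:
        if gene in annotated_genes:
            continue
        if goss_fn.has_annotation(gene):
            annotated_genes.append(gene)
        if len(annotated_genes) == k:
            break
    if len(annotated_genes) < 2:
        c.verdict = DISCARDED
        c.reason = "insufficient annotation"
        return c
    mean = _mean_pairwise_goss(annotated_genes, goss_fn)
    c.mean_member_goss = mean
    c.verdict = GOSS_PASS if mean >= mean_cutoff else DISCARDED
    if c.verdict == DISCARDED:
        c.reason = f"mean member GOSS {mean:.3f} < {mean_cutoff}"
    return c


@dataclass
class ValidationSummary:
    """Per-group mean query-gene GOSS distributions and their comparison."""

    passed_means: np.ndarray
    discarded_means: np.ndarray
    random_means: np.ndarray
    median_passed: float
    median_discarded: float
    median_random: float
    p_passed_vs_random: float


def _query_goss_mean(cluster_genes: list[str], query_gene: str,
                     goss_fn: GossScorer) -> float | None:
    genes = [g for g in cluster_genes
             if g != query_gene and goss_fn.has_annotation(g)]
    if not genes or not goss_fn.has_annotation(query_gene):
        return None
    return float(np.mean([goss_fn(query_gene, g) for g in genes]))


def validate_filtering(
    clusters: list[TapasCluster],
    goss_fn: GossScorer,
    n_random: int = 100,
    seed: int = 0,
) -> ValidationSummary:
    """Compare cluster-to-query GOSS for kept vs discarded vs random clusters.

    For each processed cluster the mean GOSS between its member genes and the
    query's parent gene is computed.  Random-membership controls of matched
    sizes are drawn (seeded) from the pool of annotated genes.  Reports group
    medians and a one-sided Mann–Whitney p-value for passed > random.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in goss_fn.ann.genes() if goss_fn.has_annotation(g)]
    passed, discarded, random_means = [], [], []
    kept_clusters = [c for c in clusters if c.verdict in (LINKED, GOSS_PASS)]
    disc_clusters = [c for c in clusters if c.verdict == DISCARDED]
    for group, sink in ((kept_clusters, passed), (disc_clusters, discarded)):
        for c in group:
            v = _query_goss_mean(c.member_genes(), c.query_gene_id, goss_fn)
            if v is not None:
                sink.append(v)
    sizes = [max(1, len(c.member_genes())) for c in kept_clusters] or [5]
    queries = [c.query_gene_id for c in kept_clusters if goss_fn.has_annotation(c.query_gene_id)]
    for i in range(n_random):
        size = sizes[i % len(sizes)]
        qgene = queries[i % len(queries)] if queries else None
        if qgene is None or len(pool) <= size:
            continue
        members = list(rng.choice([g for g in pool if g != qgene],
                                  size=min(size, len(pool) - 1), replace=False))
        v = _query_goss_mean(members, qgene, goss_fn)
        if v is not None:
            random_means.append(v)
    passed_a, disc_a, rand_a = map(np.asarray, (passed, discarded, random_means))
    p = (mann_whitney_one_sided(passed_a, rand_a)
         if passed_a.size and rand_a.size else float("nan"))
    med = lambda a: float(np.median(a)) if a.size else float("nan")
    return ValidationSummary(
        passed_means=passed_a, discarded_means=disc_a, random_means=rand_a,
        median_passed=med(passed_a), median_discarded=med(disc_a),
        median_random=med(rand_a), p_passed_vs_random=p,
    )


def run_tapas(
    queries: list[str],
    m: TimeCourseMatrix,
    net: InteractionNetwork,
    goss_fn: GossScorer,
    config: TapasConfig | None = None,
) -> tuple[list[TapasCluster], pd.DataFrame]:
    """Full pipeline per query: cluster → link → fallback filter.

    Returns the processed clusters and an edge list of functional links
    (query transcript, best-correlated member isoform, link type, score).
    Per-query failures are logged and the pipeline continues.
    """
    cfg = config or TapasConfig()
    clusters: list[TapasCluster] = []
    edges = []
    for query in queries:
        try:
            c = build_cluster(query, m, sim_threshold=cfg.sim_threshold)
            c = attach_links(c, net, goss_fn, string_cutoff=cfg.string_cutoff,
                             goss_cutoff=cfg.goss_link_cutoff)
            if c.verdict != LINKED:
                c = fallback_filter(c, goss_fn, k=cfg.fallback_k,
                                    mean_cutoff=cfg.fallback_mean_cutoff)
        except (KeyError, ValueError) as exc:
            logger.error("query %s failed: %s", query, exc)
            continue
        clusters.append(c)
        for gene, link_type, score in c.links:
            member_tid, _sim = c.best_isoform_of(gene)
            edges.append((c.query_transcript_id, member_tid, link_type, score))
    edge_df = pd.DataFrame(edges, columns=["query_transcript", "member_transcript",
                                           "link_type", "score"])
    return clusters, edge_df
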