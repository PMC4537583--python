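"""Synthetic fixtures: expression time courses, gene models, GO and networks.

Everything downstream is testable without downloads because this module
fabricates inputs with known ground truth, shaped like the staged fly
developmental RNA-seq the pipeline targets:

* **Expression** — per-gene Gaussian-bump profiles over 30 ordered stages
  (embryonic 2-hour windows through larval, white-prepupal, pupal and adult
  stages), with minor isoforms drawn from three archetypes: *switch* (a bump
  elsewhere in development at comparable magnitude — a planted high-TS case),
  *replica* (a scalar multiple of the primary — TS exactly 0 before noise)
  and *noise* (flat, barely above the expression filter — low TS).
  Multiplicative log-normal noise preserves non-negativity and scales with
  magnitude, as FPKM noise does.
* **Gene models** — primary exon chains with minors planting exactly one
  exon gain (an exon strictly inside a primary intron), one intron retention
  (two exons merged across an intron) or a boundary-shift decoy that must
  yield no event.
* **GO** — a rooted biological-process DAG whose modules share a deep term of
  known information content, with decoy genes annotated only to the root;
  written as valid OBO/GAF for round-tripping through the loaders.
* **Networks** — experimental and STRING-style edges planted within modules.

`simulate_tapas_scenario` composes these into an end-to-end benchmark with
planted functional modules and decoy queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import TranscriptModel
from .expression import TimeCourseMatrix
from .goss import AnnotationSet, GoDag
from .tapas import InteractionNetwork

__all__ = [
    "SimConfig",
    "stage_labels",
    "simulate_expression",
    "simulate_gene_models",
    "simulate_go",
    "simulate_network",
    "simulate_tapas_scenario",
    "TapasScenario",
    "write_expression_tsv",
    "write_protein_tsv",
    "write_gtf",
    "write_obo",
    "write_gaf",
    "write_ppi_tsv",
    "write_string_tsv",
]

ARCHETYPES = ("switch", "replica", "noise")

_MODENCODE_TAIL = [
    "L1", "L2", "L3_12h", "L3_PS1-2", "L3_PS3-6", "L3_PS7-9", "WPP",
    "P5", "P6", "P8", "P9-10", "P15",
    "AdF_1d", "AdM_1d", "AdF_5d", "AdM_5d", "AdF_30d", "AdM_30d",
]


def stage_labels(n_stages: int = 30) -> list[str]:
    """Ordered stage names shaped like the fly developmental series:
    embryonic 2-h windows, then larval/prepupal/pupal/adult stages."""
    embryo = [f"E{2 * i:02d}-{2 * i + 2:02d}h" for i in range(12)]
    labels = embryo + _MODENCODE_TAIL
    if n_stages <= len(labels):
        return labels[:n_stages]
    return labels + [f"S{i}" for i in range(len(labels), n_stages)]


@dataclass
class SimConfig:
    """Study conditions for the expression simulator.

    30 stages mirror the embryo-to-adult developmental series; one minor
    isoform per gene by default; archetype fractions give one planted switch
    per five genes.  Amplitudes and the low flat level of the noise archetype
    are separated so that magnitude, not only shape, distinguishes the
    archetypes — the contrast the TS score is built to exploit.
    """

    n_genes: int = 100
    n_stages: int = 30
    minors_per_gene: int = 1
    fraction_switch: float = 0.2
    fraction_replica: float = 0.4  # remainder is the flat-noise archetype
    noise_sigma: float = 0.3  # log-normal sigma of multiplicative FPKM noise
    amplitude_range: tuple[float, float] = (30.0, 100.0)
    bump_width_range: tuple[float, float] = (1.5, 3.0)
    switch_ratio_range: tuple[float, float] = (0.6, 1.0)  # minor/primary magnitude
    replica_ratio_range: tuple[float, float] = (0.2, 0.8)
    noise_level_range: tuple[float, float] = (1.1, 1.8)  # flat FPKM, just above filter
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_switch + self.fraction_replica <= 1:
            raise ValueError("archetype fractions must sum to <= 1")
        if self.n_stages < 8:
            raise ValueError("need >= 8 stages for separated bumps")


def _bump(n: int, centre: float, width: float, amplitude: float) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return amplitude * np.exp(-((t - centre) ** 2) / (2.0 * width**2))


def simulate_expression(cfg: SimConfig) -> tuple[TimeCourseMatrix, pd.DataFrame]:
    """Generate a transcript FPKM matrix with planted minor-isoform archetypes.

    Returns the matrix plus a truth table with one row per transcript
    (columns: gene_id, transcript_id, protein_key, archetype, is_minor).
    Primary profiles are Gaussian bumps; each minor isoform follows its
    archetype before multiplicative log-normal noise is applied.  Bit-
    reproducible for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_stages
    rows, truth = {}, []
    gene_map = {}
    n_switch = round(cfg.n_genes * cfg.fraction_switch)
    n_replica = round(cfg.n_genes * cfg.fraction_replica)
    archetypes = (["switch"] * n_switch + ["replica"] * n_replica
                  + ["noise"] * (cfg.n_genes - n_switch - n_replica))
    rng.shuffle(archetypes)
    for gi in range(cfg.n_genes):
        gene = f"G{gi:04d}"
        amp = rng.uniform(*cfg.amplitude_range)
        width = rng.uniform(*cfg.bump_width_range)
        # primary and switch bumps live in opposite halves of the series,
        # keeping planted switches close to orthogonal at zero noise
        early = rng.random() < 0.5
        lo, hi = (2.0, n / 2 - 2.0) if early else (n / 2 + 2.0, n - 3.0)
        centre = rng.uniform(lo, hi)
        primary = _bump(n, centre, width, amp)
        tid_p = f"{gene}.t1"
        rows[tid_p] = primary
        gene_map[tid_p] = gene
        truth.append((gene, tid_p, f"{gene}_pA", "primary", False))
        kind = archetypes[gi]
        for mi in range(cfg.minors_per_gene):
            tid = f"{gene}.t{mi + 2}"
            if kind == "switch":
                olo, ohi = (n / 2 + 2.0, n - 3.0) if early else (2.0, n / 2 - 2.0)
                mcentre = rng.uniform(olo, ohi)
                mwidth = rng.uniform(*cfg.bump_width_range)
                ratio = rng.uniform(*cfg.switch_ratio_range)
                minor = _bump(n, mcentre, mwidth, amp * ratio)
            elif kind == "replica":
                minor = primary * rng.uniform(*cfg.replica_ratio_range)
            else:
                minor = np.full(n, rng.uniform(*cfg.noise_level_range))
            rows[tid] = minor
            gene_map[tid] = gene
            truth.append((gene, tid, f"{gene}_p{chr(ord('B') + mi)}", kind, True))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=stage_labels(n))
    values.index.name = "transcript_id"
    if cfg.noise_sigma > 0:
        values = values * np.exp(cfg.noise_sigma * rng.standard_normal(values.shape))
    truth_df = pd.DataFrame(
        truth, columns=["gene_id", "transcript_id", "protein_key", "archetype", "is_minor"]
    )
    return TimeCourseMatrix(values=values, transcript_to_gene=gene_map), truth_df


# ---------------------------------------------------------------------------
# gene models with planted splice events

EVENT_KINDS = ("gain", "retention", "decoy")


def simulate_gene_models(
    n_genes: int = 100,
    seed: int = 0,
    seqname: str = "2L_sim",
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate primary/minor transcript-model pairs with planted events.

    Each gene gets a primary chain of 3–6 exons and one minor isoform built
    by one of: inserting an exon strictly inside a primary intron (one
    planted exon gain), merging two exons across an intron (one planted
    intron retention), or extending an exon boundary a few bases into its
    intron (a decoy that must produce no event).  The truth table has columns
    gene_id, primary_id, minor_id, kind, start, end (start/end NaN for
    decoys).
    """
    rng = np.random.default_rng(seed)
    models, truth = [], []
    cursor = 1000
    for gi in range(n_genes):
        gene = f"MG{gi:04d}"
        n_exons = int(rng.integers(3, 7))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(100, 301))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(200, 401))  # intron length 200-400
        cursor = pos + 5000
        strand = "+" if rng.random() < 0.5 else "-"
        tid_p, tid_m = f"{gene}.p", f"{gene}.m"
        models.append(TranscriptModel(tid_p, gene, seqname, strand, list(exons)))
        kind = EVENT_KINDS[int(rng.integers(0, 3))]
        idx = int(rng.integers(0, n_exons - 1))  # which intron to target
        intron = (exons[idx][1] + 1, exons[idx + 1][0] - 1)
        if kind == "gain":
            gap1 = int(rng.integers(1, 30))
            gap2 = int(rng.integers(1, 30))
            start = intron[0] + gap1
            end = intron[1] - gap2
            minor_exons = sorted(exons + [(start, end)])
            truth.append((gene, tid_p, tid_m, "exon_gain", start, end))
        elif kind == "retention":
            merged = (exons[idx][0], exons[idx + 1][1])
            minor_exons = exons[:idx] + [merged] + exons[idx + 2:]
            truth.append((gene, tid_p, tid_m, "intron_retention", intron[0], intron[1]))
        else:
            shift = int(rng.integers(1, 11))
            a, b = exons[idx]
            minor_exons = exons[:idx] + [(a, b + shift)] + exons[idx + 1:]
            truth.append((gene, tid_p, tid_m, "none", np.nan, np.nan))
        models.append(TranscriptModel(tid_m, gene, seqname, strand, minor_exons))
    truth_df = pd.DataFrame(
        truth, columns=["gene_id", "primary_id", "minor_id", "kind", "start", "end"]
    )
    return models, truth_df


# ---------------------------------------------------------------------------
# GO DAG, annotations and interaction networks with planted modules


def simulate_go(
    n_modules: int = 5,
    genes_per_module: int = 8,
    n_decoy_genes: int = 20,
    n_filler_genes: int = 80,
    depth: int = 2,
    seed: int = 0,
) -> tuple[GoDag, AnnotationSet, dict[str, list[str]]]:
    """Build a BP ontology with module genes sharing a deep term.

    Each module m has a parent chain root → mid → … → deep of length
    ``depth``; its genes are annotated directly to the deep term, so their
    pairwise Resnik similarity equals IC(deep) = −ln(module size / corpus).
    Decoy and filler genes are annotated only to the root (GOSS 0 to
    everything).  Returns (dag, annotations, module truth: module term →
    genes).
    """
    root = "GO:9000000"
    parents: dict[str, set[str]] = {root: set()}
    namespace = {root: "BP"}
    direct: dict[str, set[str]] = {}
    modules: dict[str, list[str]] = {}
    term_no = 1
    for mi in range(n_modules):
        chain = [root]
        for _ in range(depth):
            term = f"GO:{9000000 + term_no}"
            term_no += 1
            parents[term] = {chain[-1]}
            namespace[term] = "BP"
            chain.append(term)
        deep = chain[-1]
        genes = [f"MODG{mi}_{j}" for j in range(genes_per_module)]
        for g in genes:
            direct[g] = {deep}
        modules[deep] = genes
    for j in range(n_decoy_genes):
        direct[f"DECG{j}"] = {root}
    for j in range(n_filler_genes):
        direct[f"BGG{j:03d}"] = {root}
    dag = GoDag(parents=parents, namespace=namespace)
    return dag, AnnotationSet(direct=direct), modules


def simulate_network(
    modules: dict[str, list[str]],
    module_edge_density: float = 0.5,
    string_density: float = 0.5,
    background_genes: list[str] | None = None,
    background_density: float = 0.0,
    seed: int = 0,
) -> InteractionNetwork:
    """Plant experimental and STRING edges inside modules, noise elsewhere.

    Within-module pairs receive an experimental edge with probability
    ``module_edge_density`` and a high STRING score (850–999) with
    probability ``string_density``; background pairs get low-scored STRING
    edges (150–700) with probability ``background_density``.
    """
    rng = np.random.default_rng(seed)
    experimental: set[frozenset[str]] = set()
    string: dict[frozenset[str], int] = {}
    for genes in modules.values():
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if rng.random() < module_edge_density:
                    experimental.add(frozenset((a, b)))
                if rng.random() < string_density:
                    string[frozenset((a, b))] = int(rng.integers(850, 1000))
    bg = background_genes or []
    for i, a in enumerate(bg):
        for b in bg[i + 1:]:
            if rng.random() < background_density:
                string[frozenset((a, b))] = int(rng.integers(150, 701))
    return InteractionNetwork(experimental=experimental, string=string)


@dataclass
class TapasScenario:
    """End-to-end planted benchmark for the TAPAS pipeline."""

    matrix: TimeCourseMatrix
    dag: GoDag
    ann: AnnotationSet
    network: InteractionNetwork
    modules: dict[str, list[str]]  # deep term -> member genes
    planted_queries: list[str]  # query transcript ids, one per module
    decoy_queries: list[str]
    linked_modules: list[str]  # deep terms whose queries should resolve 'linked'
    truth: pd.DataFrame


def simulate_tapas_scenario(
    n_modules: int = 5,
    genes_per_module: int = 6,
    n_decoy_queries: int = 3,
    decoy_module_size: int = 6,
    n_filler_genes: int = 110,
    n_stages: int = 30,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> TapasScenario:
    """Compose expression, GO and network fixtures with planted neighbourhoods.

    Each functional module is a set of co-expressed genes (a shared bump
    profile) annotated to one deep BP term; its query gene carries a primary
    isoform peaking elsewhere and a minor *query* isoform tracking the module
    profile.  Modules alternate between carrying protein-interaction edges to
    the query gene (clusters resolve ``linked``) and carrying none (clusters
    must resolve ``goss_pass`` through the mean-GOSS fallback).  Decoy
    queries track co-expressed genes annotated only to the ontology root, so
    their clusters must be ``discarded``.  Filler genes pad the annotation
    corpus so the deep-term information content sits clearly above the
    fallback cutoff.
    """
    rng = np.random.default_rng(seed)
    dag, ann, modules = simulate_go(
        n_modules=n_modules, genes_per_module=genes_per_module,
        n_decoy_genes=n_decoy_queries * (decoy_module_size + 1),
        n_filler_genes=n_filler_genes, seed=seed,
    )
    deep_terms = sorted(modules)
    n = n_stages
    rows: dict[str, np.ndarray] = {}
    gene_map: dict[str, str] = {}
    truth_rows = []

    def add(tid: str, gene: str, profile: np.ndarray, role: str) -> None:
        rows[tid] = profile
        gene_map[tid] = gene
        truth_rows.append((gene, tid, role))

    centres = np.linspace(3, n - 4, n_modules + n_decoy_queries)
    planted_queries, decoy_queries, linked_modules = [], [], []
    decoy_gene_pool = [g for g in ann.direct if g.startswith("DECG")]
    di = 0
    for mi, deep in enumerate(deep_terms):
        centre = centres[mi]
        width = 2.0
        base = _bump(n, centre, width, 50.0)
        for g in modules[deep]:
            amp = rng.uniform(0.6, 1.4)
            add(f"{g}.t1", g, base * amp, "module_member")
        # query gene: annotated to the deep term; its primary is broadly
        # expressed with a dip over the module's window, so it never joins
        # any module cluster (anti-correlated with its own module, near-zero
        # with the others)
        qgene = f"QG{mi}"
        ann.direct[qgene] = {deep}
        add(f"{qgene}.t1", qgene, 60.0 - _bump(n, centre, width, 45.0), "query_primary")
        add(f"{qgene}.t2", qgene, base * rng.uniform(0.7, 1.2), "query_minor")
        planted_queries.append(f"{qgene}.t2")
        if mi % 2 == 0:
            linked_modules.append(deep)
    net_modules = {
        deep: modules[deep] + [f"QG{mi}"]
        for mi, deep in enumerate(deep_terms) if deep in linked_modules
    }
    network = simulate_network(net_modules, module_edge_density=0.6,
                               string_density=0.5, seed=seed + 1)
    for qi in range(n_decoy_queries):
        centre = centres[n_modules + qi]
        base = _bump(n, centre, 2.0, 50.0)
        members = decoy_gene_pool[di:di + decoy_module_size]
        di += decoy_module_size
        for g in members:
            add(f"{g}.t1", g, base * rng.uniform(0.6, 1.4), "decoy_member")
        qgene = decoy_gene_pool[di]
        di += 1
        add(f"{qgene}.t1", qgene, 60.0 - _bump(n, centre, 2.0, 45.0), "decoy_primary")
        add(f"{qgene}.t2", qgene, base * rng.uniform(0.7, 1.2), "decoy_minor")
        decoy_queries.append(f"{qgene}.t2")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=stage_labels(n))
    values.index.name = "transcript_id"
    if noise_sigma > 0:
        values = values * np.exp(noise_sigma * rng.standard_normal(values.shape))
    matrix = TimeCourseMatrix(values=values, transcript_to_gene=gene_map)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "transcript_id", "role"])
    return TapasScenario(
        matrix=matrix, dag=dag, ann=ann, network=network, modules=modules,
        planted_queries=planted_queries, decoy_queries=decoy_queries,
        linked_modules=linked_modules, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers: emit exactly the formats the loaders read


def write_expression_tsv(m: TimeCourseMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.insert(0, "gene_id", [m.transcript_to_gene[t] for t in df.index])
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")


def write_protein_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    """Two-column transcript → protein-key table from an expression truth frame."""
    truth[["transcript_id", "protein_key"]].to_csv(path, sep="\t", header=False, index=False)


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in models:
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(f"{t.seqname}\tsim\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n")


def write_obo(dag: GoDag, path: str | Path) -> None:
    code_to_ns = {"BP": "biological_process", "MF": "molecular_function",
                  "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            fh.write(f"namespace: {code_to_ns.get(dag.namespace[term], 'biological_process')}\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")


def write_gaf(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(ann.direct):
            for term in sorted(ann.direct[gene]):
                cols = ["SYN", gene, gene, "", term, "SYN:0001", "IDA", "", "P",
                        gene, "", "protein", "taxon:7227", "20150101", "SYN", "", ""]
                fh.write("\t".join(cols) + "\n")


def write_ppi_tsv(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for edge in sorted(tuple(sorted(e)) for e in net.experimental):
            fh.write(f"{edge[0]}\t{edge[1]}\n")


def write_string_tsv(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for edge, score in sorted((tuple(sorted(e)), s) for e, s in net.string.items()):
            fh.write(f"{edge[0]}\t{edge[1]}\t{score}\n")
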