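"""Transcript-level expression time courses and isoform designation.

The analysis operates on per-transcript FPKM vectors over an ordered series of
developmental stages (embryonic hours through larval, prepupal, pupal and adult
stages).  A gene is retained as a *multi-protein gene* if, after discarding
transcripts never expressed above a minimal FPKM, at least two distinct protein
sequences remain among its transcripts.  Within each retained gene:

* the **primary** isoform is the transcript with the highest mean expression
  over the whole time course;
* the **secondary** isoform is the most highly expressed transcript encoding a
  protein different from the primary's;
* **minor** isoforms are all transcripts encoding a protein different from the
  primary's.

Mean expression is the unweighted arithmetic mean over all stages; the stage
axis is an ordered categorical, never interpolated.  Ties in mean expression
are broken lexicographically by transcript id so designation is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseMatrix",
    "IsoformRecord",
    "GeneIsoformSet",
    "load_expression",
    "load_protein_map",
    "filter_multiprotein_genes",
    "designate_isoforms",
]


@dataclass
class TimeCourseMatrix:
    """Per-transcript FPKM vectors over ordered, labelled developmental stages.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id, one non-negative float column per
        stage, columns in developmental order.
    transcript_to_gene
        Mapping from transcript id to its (single) gene id.
    """

    values: pd.DataFrame
    transcript_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate transcript ids: {list(dupes)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.values.index) - set(self.transcript_to_gene)
        if missing:
            raise ValueError(f"transcripts without a gene mapping: {sorted(missing)[:5]}")

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def profile(self, transcript_id: str) -> np.ndarray:
        """FPKM vector of one transcript, in stage order."""
        return self.values.loc[transcript_id].to_numpy(dtype=float)

    def gene_of(self, transcript_id: str) -> str:
        return self.transcript_to_gene[transcript_id]

    def gene_profile(self, gene_id: str) -> np.ndarray:
        """Gene-level expression profile: per-stage sum over all isoforms."""
        tids = [t for t in self.values.index if self.transcript_to_gene[t] == gene_id]
        if not tids:
            raise KeyError(f"no transcripts for gene {gene_id}")
        return self.values.loc[tids].sum(axis=0).to_numpy(dtype=float)

    def subset(self, transcript_ids: Sequence[str]) -> "TimeCourseMatrix":
        tids = list(transcript_ids)
        return TimeCourseMatrix(
            values=self.values.loc[tids],
            transcript_to_gene={t: self.transcript_to_gene[t] for t in tids},
        )


@dataclass(frozen=True)
class IsoformRecord:
    transcript_id: str
    protein_key: str
    mean_expression: float


@dataclass
class GeneIsoformSet:
    """A gene's surviving transcripts, ranked by mean expression.

    ``transcripts`` is sorted by mean expression descending (ties broken by
    transcript id); ``primary_id`` is always its first element.  ``minor_ids``
    are all transcripts whose protein differs from the primary's, and
    ``secondary_id`` is the most expressed of those (None only before
    designation or if no distinct protein exists).
    """

    gene_id: str
    transcripts: list[IsoformRecord]
    primary_id: str | None = None
    secondary_id: str | None = None
    minor_ids: list[str] = field(default_factory=list)

    def record(self, transcript_id: str) -> IsoformRecord:
        for rec in self.transcripts:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)

    @property
    def n_proteins(self) -> int:
        return len({r.protein_key for r in self.transcripts})


def load_expression(path: str | Path) -> TimeCourseMatrix:
    """Read a tab-separated expression table into a :class:`TimeCourseMatrix`.

    The file must have a header row ``transcript_id<TAB>gene_id<TAB><stage>...``
    followed by one row per transcript.  Stage order is preserved from the
    header.  Rows containing a negative FPKM are rejected with a logged error;
    a duplicated transcript id is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected transcript_id, gene_id and >=1 stage column")
    tid_col, gene_col = df.columns[0], df.columns[1]
    if df[tid_col].duplicated().any():
        dupes = df.loc[df[tid_col].duplicated(), tid_col].unique()
        raise ValueError(f"{path}: duplicate transcript_id(s): {list(dupes)[:5]}")
    stage_cols = list(df.columns[2:])
    vals = df[stage_cols].apply(pd.to_numeric)
    bad = (vals < 0).any(axis=1)
    if bad.any():
        for tid in df.loc[bad, tid_col]:
            logger.error("dropping transcript %s: negative FPKM", tid)
        df, vals = df.loc[~bad], vals.loc[~bad]
    values = vals.copy()
    values.index = pd.Index(df[tid_col], name="transcript_id")
    mapping = dict(zip(df[tid_col], df[gene_col]))
    return TimeCourseMatrix(values=values, transcript_to_gene=mapping)


def load_protein_map(path: str | Path) -> dict[str, str]:
    """Read a transcript→protein mapping.

    Accepts either a FASTA of protein sequences keyed by transcript id (the
    protein key is the exact sequence string, so identical proteins compare
    equal) or a two-column TSV ``transcript_id<TAB>protein_key``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        mapping: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            mapping[rec.id] = str(rec.seq)
        return mapping
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "protein_key"],
                     dtype=str, comment="#")
    return dict(zip(df["transcript_id"], df["protein_key"]))


def _sorted_records(records: list[IsoformRecord]) -> list[IsoformRecord]:
    # descending mean expression, lexicographic transcript id on ties
    return sorted(records, key=lambda r: (-r.mean_expression, r.transcript_id))


def filter_multiprotein_genes(
    m: TimeCourseMatrix,
    proteins: Mapping[str, str],
    min_fpkm: float = 1.0,
) -> list[GeneIsoformSet]:
    """Apply the multi-protein-gene filter and rank surviving isoforms.

    A transcript survives only if its FPKM exceeds ``min_fpkm`` (strictly) in
    at least one stage.  A gene is kept only if its surviving transcripts carry
    at least two distinct protein keys.  Every surviving transcript must be
    present in ``proteins``; a missing entry is a hard error naming the
    transcript.  Returned sets are designated (primary/secondary/minor) and
    sorted by gene id.
    """
    maxima = m.values.max(axis=1)
    survivors = maxima.index[maxima > min_fpkm]
    by_gene: dict[str, list[IsoformRecord]] = {}
    for tid in survivors:
        if tid not in proteins:
            raise KeyError(f"transcript {tid} missing from protein map")
        rec = IsoformRecord(
            transcript_id=tid,
            protein_key=proteins[tid],
            mean_expression=float(m.values.loc[tid].mean()),
        )
        by_gene.setdefault(m.transcript_to_gene[tid], []).append(rec)
    out = []
    for gene_id in sorted(by_gene):
        records = _sorted_records(by_gene[gene_id])
        if len({r.protein_key for r in records}) >= 2:
            out.append(designate_isoforms(GeneIsoformSet(gene_id=gene_id, transcripts=records)))
    return out


def designate_isoforms(g: GeneIsoformSet) -> GeneIsoformSet:
    """Designate primary, secondary and minor isoforms of a gene.

    Primary is the transcript with maximum mean expression (ties broken
    lexicographically); secondary is the highest-mean transcript whose protein
    differs from the primary's; minors are all transcripts with a protein
    different from the primary's.  Idempotent and independent of the input
    ordering of ``g.transcripts``.
    """
    if len(g.transcripts) < 2 or g.n_proteins < 2:
        raise ValueError(
            f"gene {g.gene_id}: designation requires >=2 transcripts with >=2 distinct proteins"
        )
    ranked = _sorted_records(list(g.transcripts))
    primary = ranked[0]
    minors = [r.transcript_id for r in ranked[1:] if r.protein_key != primary.protein_key]
    return GeneIsoformSet(
        gene_id=g.gene_id,
        transcripts=ranked,
        primary_id=primary.transcript_id,
        secondary_id=minors[0] if minors else None,
        minor_ids=minors,
    )
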