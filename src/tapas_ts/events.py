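"""Exon-gain and intron-retention classification between isoform pairs.

Transcript models come from GTF (1-based, inclusive coordinates, preserved
internally).  Comparing a minor isoform against its gene's primary isoform:

* **exon gain** — a minor exon sharing no base with any primary exon;
* **intron retention** — a minor exon whose interval fully contains a primary
  intron (one event per fully covered intron, so a single read-through exon
  spanning several introns yields several events).

Gained exons can be filtered by an evolutionary Conservation Index (CI): an
event is flagged conserved when a matching conservation record scores at or
above a cutoff (default 5, separating the conserved mode of the bimodal CI
distribution).  Events with no matching record keep ``conserved=None``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "SpliceEvent",
    "ConservationRecord",
    "load_gtf",
    "load_conservation",
    "introns",
    "classify_events",
    "flag_conserved",
    "CI_CUTOFF",
]

#: default Conservation Index cutoff separating conserved from non-conserved exons
CI_CUTOFF = 5.0

EXON_GAIN = "exon_gain"
INTRON_RETENTION = "intron_retention"


@dataclass
class TranscriptModel:
    """Exon structure of one transcript; coordinates 1-based inclusive."""

    transcript_id: str
    gene_id: str
    seqname: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >=1 exon")
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"{self.transcript_id}: exon end {end} < start {start}")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class SpliceEvent:
    kind: str  # EXON_GAIN or INTRON_RETENTION
    gene_id: str
    primary_id: str
    minor_id: str
    interval: tuple[int, int]
    conserved: bool | None = None


@dataclass(frozen=True)
class ConservationRecord:
    seqname: str
    interval: tuple[int, int]
    ci: float


def load_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into :class:`TranscriptModel` objects.

    Exon lines are grouped per transcript and sorted; out-of-order input is
    fine.  An exon missing its ``transcript_id`` attribute, or with
    end < start, is a hard error reporting the offending line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None)
            if feat.featuretype != "exon":
                continue
            if "transcript_id" not in feat.attributes:
                raise ValueError(f"{path}:{lineno}: exon missing transcript_id attribute")
            if "gene_id" not in feat.attributes:
                raise ValueError(f"{path}:{lineno}: exon missing gene_id attribute")
            if feat.end < feat.start:
                raise ValueError(f"{path}:{lineno}: exon end {feat.end} < start {feat.start}")
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            if tid in meta and meta[tid] != (gid, feat.seqid, feat.strand):
                raise ValueError(f"{path}:{lineno}: transcript {tid} with inconsistent gene/seqname/strand")
            meta[tid] = (gid, feat.seqid, feat.strand)
            exons.setdefault(tid, []).append((feat.start, feat.end))
    return [
        TranscriptModel(transcript_id=tid, gene_id=meta[tid][0], seqname=meta[tid][1],
                        strand=meta[tid][2], exons=exons[tid])
        for tid in sorted(exons)
    ]


def load_conservation(path: str | Path) -> list[ConservationRecord]:
    """Read a conservation TSV: ``seqname<TAB>start<TAB>end<TAB>ci``."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("seqname"):
                continue
            seqname, start, end, ci = line.split("\t")[:4]
            records.append(ConservationRecord(seqname, (int(start), int(end)), float(ci)))
    return records


def introns(t: TranscriptModel) -> list[tuple[int, int]]:
    """Intervals between consecutive exons; empty for single-exon transcripts."""
    out = []
    for (_, a_end), (b_start, _) in zip(t.exons, t.exons[1:]):
        out.append((a_end + 1, b_start - 1))
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    # >=1 shared base, closed intervals
    return a[0] <= b[1] and b[0] <= a[1]


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def classify_events(primary: TranscriptModel, minor: TranscriptModel) -> list[SpliceEvent]:
    """Classify gain/retention events of ``minor`` relative to ``primary``.

    Returns exon-gain events (interval = the gained minor exon) followed by
    intron-retention events (interval = the retained primary intron), in
    genomic order.  Both transcripts must belong to the same gene on the same
    seqname and strand.
    """
    if primary.gene_id != minor.gene_id:
        raise ValueError(f"cross-gene comparison: {primary.gene_id} vs {minor.gene_id}")
    if primary.seqname != minor.seqname:
        raise ValueError(f"seqname mismatch: {primary.seqname} vs {minor.seqname}")
    if primary.strand != minor.strand:
        raise ValueError(f"strand mismatch for gene {primary.gene_id}")
    events: list[SpliceEvent] = []
    for exon in minor.exons:
        if not any(_overlaps(exon, pex) for pex in primary.exons):
            events.append(SpliceEvent(EXON_GAIN, minor.gene_id, primary.transcript_id,
                                      minor.transcript_id, exon))
    for intron in introns(primary):
        if intron[0] > intron[1]:  # zero-length gap between abutting exons
            continue
        if any(_contains(exon, intron) for exon in minor.exons):
            events.append(SpliceEvent(INTRON_RETENTION, minor.gene_id, primary.transcript_id,
                                      minor.transcript_id, intron))
    events.sort(key=lambda e: (e.interval, e.kind))
    return events


def classify_events_symmetric(
    primary: TranscriptModel, minor: TranscriptModel
) -> list[SpliceEvent]:
    """Events in both directions; the swapped call reports exon *losses*
    (exons of the primary absent from the minor) as gains of the primary."""
    return classify_events(primary, minor) + classify_events(minor, primary)


def flag_conserved(
    events: Iterable[SpliceEvent],
    cons: Iterable[ConservationRecord],
    cutoff: float = CI_CUTOFF,
    seqname_of: dict[str, str] | None = None,
) -> list[SpliceEvent]:
    """Attach conservation verdicts to events.

    A record matches an event by exact (seqname, interval) coordinates first;
    failing that, the record with maximal overlap on the same seqname is used
    (annotation versions shift exon bounds by a few bases).  ``conserved`` is
    True iff the matching record's CI >= ``cutoff``; events with no matching
    record keep ``conserved=None``.  ``seqname_of`` maps gene_id to seqname
    when events alone do not carry it; by default records on any seqname whose
    interval matches are considered only via the exact-coordinate route.
    """
    cons = list(cons)
    exact: dict[tuple[str, int, int], float] = {}
    trees: dict[str, IntervalTree] = {}
    for rec in cons:
        key = (rec.seqname, rec.interval[0], rec.interval[1])
        exact[key] = max(rec.ci, exact.get(key, float("-inf")))
        trees.setdefault(rec.seqname, IntervalTree()).addi(
            rec.interval[0], rec.interval[1] + 1, rec.ci
        )
    out = []
    for ev in events:
        seqname = (seqname_of or {}).get(ev.gene_id)
        ci = None
        candidates = [seqname] if seqname else list(trees)
        for sn in candidates:
            key = (sn, ev.interval[0], ev.interval[1])
            if key in exact:
                ci = exact[key]
                break
        if ci is None:
            best_overlap = 0
            for sn in candidates:
                if sn not in trees:
                    continue
                for hit in trees[sn].overlap(ev.interval[0], ev.interval[1] + 1):
                    ov = min(hit.end - 1, ev.interval[1]) - max(hit.begin, ev.interval[0]) + 1
                    if ov > best_overlap:
                        best_overlap, ci = ov, hit.data
        if ci is None:
            out.append(ev)
        else:
            out.append(SpliceEvent(ev.kind, ev.gene_id, ev.primary_id, ev.minor_id,
                                   ev.interval, conserved=bool(ci >= cutoff)))
    return out
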