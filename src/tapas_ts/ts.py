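"""The Time-course Switch (TS) score.

Stack the primary and minor isoform expression profiles as the two rows of a
matrix X and take its singular values s1 >= s2 >= 0.  The score is

    TS = 2 * (1 - s1 / (s1 + s2))

If the minor profile is a scalar multiple of the primary (same shape, any
magnitude) X has rank 1, s2 = 0 and TS = 0.  TS reaches 1 only when the two
profiles are orthogonal *and* of equal Euclidean norm, so the score rises both
with shape divergence and with magnitude balance — unlike 1 − Pearson, which
ignores magnitude entirely and can rank a flat, barely expressed minor isoform
as maximally dissimilar.  TS is symmetric in its arguments and invariant to a
common positive rescaling of both profiles.

A gene is called *High-TS* when the primary–secondary TS score strictly
exceeds a threshold (default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .expression import GeneIsoformSet, TimeCourseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TSResult",
    "ts_score",
    "ts_scores_for_genes",
    "pearson_dissimilarity",
    "euclidean_distance",
    "HIGH_TS_THRESHOLD",
]

#: default High-TS threshold; genes with primary–secondary TS > this are High-TS
HIGH_TS_THRESHOLD = 0.5


@dataclass(frozen=True)
class TSResult:
    gene_id: str
    minor_transcript_id: str
    ts: float
    is_high_ts: bool


def _as_profile(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("profiles must be 1-D with at least two stages")
    if (a < 0).any():
        raise ValueError("profiles must be non-negative")
    return a


def ts_score(p, q, log1p: bool = False) -> float:
    """TS score between two expression profiles.

    Parameters
    ----------
    p, q
        Non-negative FPKM vectors of equal length >= 2.  Profiles enter the
        SVD untransformed by default — magnitude sensitivity is the point of
        the score; set ``log1p=True`` to compress dynamic range first.

    Returns
    -------
    float in [0, 1].  0 when the two profiles are proportional; 1 when they
    are orthogonal with equal norms.

    Raises
    ------
    ValueError
        If lengths differ, entries are negative, or both vectors are entirely
        zero (the score is 0/0-undefined there; an all-zero profile reaching
        this point indicates a missing upstream expression filter).
    """
    p, q = _as_profile(p), _as_profile(q)
    if p.shape != q.shape:
        raise ValueError(f"profile lengths differ: {p.size} vs {q.size}")
    if not (p.any() or q.any()):
        raise ValueError("TS score undefined: both profiles are all-zero")
    x = np.vstack([p, q])
    if log1p:
        x = np.log1p(x)
    s = np.linalg.svd(x, compute_uv=False)
    return float(2.0 * (1.0 - s[0] / s.sum()))


def pearson_dissimilarity(p, q) -> float:
    """1 − Pearson correlation between two profiles; range [0, 2].

    Shape-only dissimilarity used as a foil for TS: a flat, low-expression
    minor isoform gets a large value here despite being plausible noise.
    Constant vectors have undefined correlation and raise ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("profiles must be equal-length 1-D vectors, length >= 2")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("Pearson correlation undefined for a constant profile")
    r = sps.pearsonr(p, q).statistic
    return float(1.0 - r)


def euclidean_distance(p, q) -> float:
    """Plain Euclidean distance between two profiles (comparison metric)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have equal length")
    return float(np.linalg.norm(p - q))


def ts_scores_for_genes(
    genes: list[GeneIsoformSet],
    m: TimeCourseMatrix,
    threshold: float = HIGH_TS_THRESHOLD,
    all_minor_pairs: bool = False,
    log1p: bool = False,
) -> list[TSResult]:
    """Score primary–minor profile pairs for designated genes.

    By default one :class:`TSResult` per gene, for the primary–secondary pair
    (the gene-level TS used for High-TS designation).  With
    ``all_minor_pairs=True``, every primary–minor pair is scored.
    ``is_high_ts`` is set where ts > ``threshold`` (strict).  Genes whose
    profiles are missing from ``m``, or whose pairs are degenerate (both
    profiles all-zero), are skipped with a warning.
    """
    results: list[TSResult] = []
    for g in genes:
        if g.primary_id is None:
            raise ValueError(f"gene {g.gene_id} has not been designated")
        targets = g.minor_ids if all_minor_pairs else g.minor_ids[:1]
        for minor_id in targets:
            try:
                p = m.profile(g.primary_id)
                q = m.profile(minor_id)
            except KeyError as exc:
                logger.warning("gene %s: missing profile %s, skipped", g.gene_id, exc)
                continue
            try:
                ts = ts_score(p, q, log1p=log1p)
            except ValueError as exc:
                logger.warning("gene %s/%s: %s, skipped", g.gene_id, minor_id, exc)
                continue
            results.append(
                TSResult(
                    gene_id=g.gene_id,
                    minor_transcript_id=minor_id,
                    ts=ts,
                    is_high_ts=ts > threshold,
                )
            )
    return results
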