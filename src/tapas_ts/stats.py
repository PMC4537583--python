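"""Enrichment and bias-control statistics.

All hypothesis tests are one-sided.  Fisher's exact test is the one-sided
hypergeometric tail for 2×2 tables; the Mann–Whitney rank test uses exact
enumeration for small samples and a tie-corrected normal approximation
otherwise; multiple testing is controlled by Benjamini–Hochberg.  GO-term
enrichment skips terms with fewer than a minimum number of background
annotations (default 10).  Two bias controls are provided: a permutation null
that shuffles per-gene scores while keeping event annotations fixed, and a
greedy Euclidean profile-matching that pairs each case gene with the unused
control gene with the most similar gene-level expression profile.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .goss import AnnotationSet, GoDag, propagate_annotations

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "MatchedPairs",
    "GeneLabelTable",
    "PermutationNull",
    "fisher_one_sided",
    "mann_whitney_one_sided",
    "bh_correct",
    "go_enrichment",
    "permute_ts_null",
    "euclidean_match",
    "stratified_enrichment",
    "load_labels",
]

# exact Mann-Whitney enumeration bounds; beyond this the normal approximation is used
_MW_EXACT_MIN = 8
_MW_EXACT_TOTAL = 20


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    a: int  # study ∩ property
    b: int  # study \ property
    c: int  # rest ∩ property
    d: int  # rest \ property
    p_one_sided: float
    q_bh: float | None = None
    direction: str = "greater"
    flagged: bool = False  # degenerate margin


@dataclass
class MatchedPairs:
    pairs: list[tuple[str, str, float]]  # (case gene, control gene, distance)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case", "control", "distance"])


class GeneLabelTable:
    """Boolean gene flags (essential, singleton, domain classes, high_ts ...).

    Backed by a DataFrame indexed by gene with nullable-boolean columns;
    missing values mean the flag is unknown for that gene.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.astype("boolean")

    @classmethod
    def from_records(cls, records) -> "GeneLabelTable":
        """Build from (gene_id, flag_name, value) triples."""
        df = pd.DataFrame(records, columns=["gene_id", "flag", "value"])
        wide = df.pivot_table(index="gene_id", columns="flag", values="value",
                              aggfunc="last")
        return cls(wide)

    def genes(self) -> list[str]:
        return list(self.frame.index)


def load_labels(path) -> GeneLabelTable:
    """Read a label TSV ``gene_id<TAB>flag_name<TAB>0/1``."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "flag", "value"], comment="#")
    df["value"] = df["value"].astype(int).astype(bool)
    return GeneLabelTable.from_records(df.itertuples(index=False, name=None))


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact test for over-representation.

    Tests whether the top-left cell ``a`` of the 2×2 table [[a, b], [c, d]] is
    larger than expected under the hypergeometric null.  Degenerate tables
    with an empty margin return p = 1 with a warning.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.warning("Fisher table (%d,%d,%d,%d) has an empty margin; p=1", a, b, c, d)
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def _mw_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided tail P(rank-sum of x >= observed) by enumeration.

    Midranks handle ties; every assignment of the pooled values to the two
    groups is enumerated, so this is only used for small samples.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    total = 0
    hits = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(combo)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_one_sided(x, y) -> float:
    """One-sided Mann–Whitney rank test: is ``x`` stochastically greater?

    Exact enumeration (tie-aware) when min(n, m) <= 8 and n + m <= 20, else
    the tie-corrected normal approximation with continuity correction.  If
    every pooled value is identical the test is uninformative and returns the
    0.5 boundary with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("all values identical; Mann-Whitney p set to 0.5")
        return 0.5
    if min(x.size, y.size) <= _MW_EXACT_MIN and x.size + y.size <= _MW_EXACT_TOTAL:
        return _mw_exact(x, y)
    return float(sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")[1])


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def go_enrichment(
    study: set[str],
    background: set[str],
    ann: AnnotationSet,
    dag: GoDag,
    namespace: str = "BP",
    min_term_size: int = 10,
) -> list[EnrichmentResult]:
    """Per-term one-sided Fisher enrichment of ``study`` against ``background``.

    Annotations are true-path propagated; terms annotated to fewer than
    ``min_term_size`` background genes are not tested.  BH correction is
    applied over the tested terms only.  Results are sorted by p-value.
    """
    if not study:
        return []
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    term_genes = propagate_annotations(dag, ann)
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for term in sorted(term_genes):
        if dag.namespace.get(term) != namespace:
            continue
        bg_term = term_genes[term] & background
        if len(bg_term) < min_term_size:
            continue
        a = len(bg_term & study)
        b = n_study - a
        c = len(bg_term) - a
        d = n_bg - n_study - c
        rows.append((term, a, b, c, d, fisher_one_sided(a, b, c, d)))
    if not rows:
        return []
    qvals = bh_correct([r[5] for r in rows])
    results = [
        EnrichmentResult(category=t, a=a, b=b, c=c, d=d, p_one_sided=p, q_bh=float(q))
        for (t, a, b, c, d, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_one_sided, r.category))
    return results


@dataclass
class PermutationNull:
    """Null TS distributions from shuffling scores across genes."""

    observed_median: dict[str, float]  # event kind -> observed median TS
    null_medians: dict[str, np.ndarray]  # event kind -> per-permutation medians
    p_empirical: dict[str, float]
    direction: dict[str, str]


def permute_ts_null(
    ts_by_gene: dict[str, float],
    events_by_gene: dict[str, str],
    n_perm: int,
    seed: int,
    directions: dict[str, str] | None = None,
) -> PermutationNull:
    """Permutation null for per-event-kind TS medians.

    TS scores are randomly permuted across genes while each gene keeps its
    event annotation, so each permutation yields a null median TS per event
    kind.  The empirical one-sided p for kind k is (r + 1) / (n_perm + 1),
    with r the number of permutations whose null median is at least as
    extreme as the observed one in the direction of interest (default
    'greater'; pass ``directions={'intron_retention': 'less'}`` to test a
    deficit).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    genes = sorted(ts_by_gene)
    if len(genes) < 2:
        raise ValueError("permutation null requires >= 2 genes")
    ts = np.array([ts_by_gene[g] for g in genes])
    kinds = sorted(set(events_by_gene.values()))
    masks = {k: np.array([events_by_gene.get(g) == k for g in genes]) for k in kinds}
    observed = {k: float(np.median(ts[masks[k]])) for k in kinds if masks[k].any()}
    rng = np.random.default_rng(seed)
    null = {k: np.empty(n_perm) for k in observed}
    for i in range(n_perm):
        perm = rng.permutation(ts)
        for k in observed:
            null[k][i] = np.median(perm[masks[k]])
    directions = directions or {}
    p, dirs = {}, {}
    for k in observed:
        d = directions.get(k, "greater")
        if d == "greater":
            r = int((null[k] >= observed[k] - 1e-12).sum())
        else:
            r = int((null[k] <= observed[k] + 1e-12).sum())
        p[k] = (r + 1) / (n_perm + 1)
        dirs[k] = d
    return PermutationNull(observed_median=observed, null_medians=null,
                           p_empirical=p, direction=dirs)


def euclidean_match(
    high_ts: list[str],
    pool: list[str],
    gene_profiles: dict[str, np.ndarray],
) -> MatchedPairs:
    """Greedy iterative profile matching of case genes to unused controls.

    Case genes are processed in descending total expression (ties broken
    lexicographically); each takes the not-yet-used pool gene at minimum
    Euclidean distance between gene-level (isoform-summed) expression
    profiles, ties broken lexicographically.  Once paired, a control cannot
    be reused.  The pairing is injective by construction.
    """
    if len(pool) < len(high_ts):
        raise ValueError(f"control pool ({len(pool)}) smaller than case set ({len(high_ts)})")
    order = sorted(high_ts, key=lambda g: (-float(np.sum(gene_profiles[g])), g))
    available = sorted(set(pool))
    pairs = []
    for case in order:
        cp = np.asarray(gene_profiles[case], dtype=float)
        if not available:
            raise ValueError("control pool exhausted")
        best = min(available,
                   key=lambda g: (float(np.linalg.norm(cp - gene_profiles[g])), g))
        pairs.append((case, best, float(np.linalg.norm(cp - gene_profiles[best]))))
        available.remove(best)
    return MatchedPairs(pairs=pairs)


def stratified_enrichment(
    labels: GeneLabelTable,
    study_flag: str,
    target_flag: str,
    strata: dict[str, bool] | None = None,
) -> EnrichmentResult:
    """Re-test a 2×2 enrichment within a restricted universe.

    The universe is restricted to genes satisfying every condition in
    ``strata`` (flag name → required boolean; e.g. ``{"singleton": True}`` or
    ``{"dbd_domain": False}``) with both ``study_flag`` and ``target_flag``
    known.  An empty margin flags the result and forces p = 1.
    """
    df = labels.frame
    for flag in [study_flag, target_flag, *(strata or {})]:
        if flag not in df.columns:
            raise KeyError(f"unknown flag {flag!r}")
    mask = df[study_flag].notna() & df[target_flag].notna()
    for flag, wanted in (strata or {}).items():
        mask &= df[flag].notna() & (df[flag] == wanted)
    sub = df.loc[mask]
    study = sub[study_flag].astype(bool)
    target = sub[target_flag].astype(bool)
    a = int((study & target).sum())
    b = int((study & ~target).sum())
    c = int((~study & target).sum())
    d = int((~study & ~target).sum())
    flagged = a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0
    p = 1.0 if flagged else fisher_one_sided(a, b, c, d)
    name = f"{target_flag}|{study_flag}" + (
        "" if not strata else "[" + ",".join(f"{k}={v}" for k, v in sorted(strata.items())) + "]"
    )
    return EnrichmentResult(category=name, a=a, b=b, c=c, d=d,
                            p_one_sided=p, flagged=flagged)
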