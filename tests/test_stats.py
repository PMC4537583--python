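import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from tapas_ts.goss import AnnotationSet
from tapas_ts.stats import (
    GeneLabelTable,
    bh_correct,
    euclidean_match,
    fisher_one_sided,
    go_enrichment,
    mann_whitney_one_sided,
    permute_ts_null,
    stratified_enrichment,
)

# ---------------------------------------------------------------------------
# enumeration oracles


def hypergeom_tail(a, b, c, d):
    """P(top-left cell >= a) with margins fixed: direct hypergeometric sum."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (math.comb(col1, k) * math.comb(n - col1, row1 - k)) / math.comb(n, row1)
    return p


def mw_tail(x, y):
    """P(rank-sum of the x-group >= observed) over all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if ranks[list(combo)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


class TestFisher:
    def test_perfect_separation(self):
        assert fisher_one_sided(5, 0, 0, 5) == pytest.approx(1 / math.comb(10, 5),
                                                             abs=1e-12)

    def test_balanced_table(self):
        assert fisher_one_sided(1, 1, 1, 1) == pytest.approx(5 / 6, abs=1e-12)

    def test_zero_observed_cell_cannot_be_enriched(self):
        assert fisher_one_sided(0, 5, 3, 4) == pytest.approx(
            hypergeom_tail(0, 5, 3, 4), abs=1e-12)
        assert fisher_one_sided(0, 5, 3, 4) == pytest.approx(1.0, abs=1e-12)

    def test_empty_margin_returns_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_one_sided(0, 0, 3, 4) == 1.0
        assert "margin" in caplog.text

    def test_random_small_tables_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_one_sided(a, b, c, d) == pytest.approx(
                hypergeom_tail(a, b, c, d), abs=1e-12)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 1, 1, 1)


class TestMannWhitney:
    def test_complete_separation_exact(self):
        assert mann_whitney_one_sided([4, 5, 6], [1, 2, 3]) == pytest.approx(
            1 / math.comb(6, 3), abs=1e-12)

    def test_random_small_samples_match_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n, m = rng.integers(2, 7, size=2)
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.integers(0, 6, size=m).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            assert mann_whitney_one_sided(x, y) == pytest.approx(mw_tail(x, y),
                                                                 abs=1e-12)

    def test_identical_samples_centre_on_half(self):
        # exact path: the tail at the centre includes the atom P(U = centre),
        # so identical samples sit at or just above 0.5
        p = mann_whitney_one_sided([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(mw_tail([1, 2, 3], [1, 2, 3]), abs=1e-12)
        assert 0.5 <= p <= 1.0
        # asymptotic path: large identical samples give p ~ 0.5
        big = list(range(30))
        assert mann_whitney_one_sided(big, big) == pytest.approx(0.5, abs=0.02)

    def test_all_values_identical_is_half_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert mann_whitney_one_sided([2, 2], [2, 2, 2]) == 0.5
        assert "identical" in caplog.text

    def test_swapped_arguments_complement_without_ties(self):
        x, y = [1.5, 3.2, 7.1], [2.0, 4.4]
        p_fwd = mann_whitney_one_sided(x, y)
        p_rev = mann_whitney_one_sided(y, x)
        # exact tails share the atom at the observed statistic
        atom = mw_tail(x, y) + mw_tail(y, x) - 1
        assert p_fwd + p_rev == pytest.approx(1 + atom, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1, 2])


class TestBH:
    def test_step_up_closed_form(self):
        q = bh_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_and_unit_pvalues(self):
        assert bh_correct([0.5])[0] == pytest.approx(0.5)
        np.testing.assert_allclose(bh_correct([1.0, 1.0]), [1.0, 1.0])

    def test_q_dominates_p_and_matches_min_form(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        q = bh_correct(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        # closed form: q_(i) = min_{j>=i} p_(j) * m / j on the sorted scale
        order = np.argsort(p)
        ps = p[order]
        m = len(p)
        expect = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(expect, 1), atol=1e-12)


class TestGoEnrichment:
    def test_small_terms_skipped_and_perfect_term_top(self, toy_dag):
        # term GO:0000004 covers the full 15-gene study; GO:0000005 has 9
        # background genes, below the min-size cutoff
        direct = {f"s{i}": {"GO:0000004"} for i in range(15)}
        direct |= {f"n{i}": {"GO:0000005"} for i in range(9)}
        direct |= {f"r{i}": {"GO:0000001"} for i in range(76)}
        ann = AnnotationSet(direct=direct)
        background = set(direct)
        study = {f"s{i}" for i in range(15)}
        results = go_enrichment(study, background, ann, toy_dag, min_term_size=10)
        terms = {r.category for r in results}
        assert "GO:0000005" not in terms
        # propagation carries the study genes to the parent term too, so the
        # deep term and its parent tie at the top
        assert {r.category for r in results[:2]} == {"GO:0000002", "GO:0000004"}
        deep = next(r for r in results if r.category == "GO:0000004")
        assert (deep.a, deep.b) == (15, 0)
        assert deep.p_one_sided == pytest.approx(
            fisher_one_sided(15, 0, 0, 85), abs=1e-12)

    def test_empty_study_returns_empty(self, toy_dag, toy_annotations):
        assert go_enrichment(set(), {"g0"}, toy_annotations, toy_dag) == []

    def test_random_study_rarely_significant(self, toy_dag):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(200)]
        direct = {g: {rng.choice(["GO:0000004", "GO:0000005", "GO:0000001"])}
                  for g in genes}
        ann = AnnotationSet(direct=direct)
        background = set(genes)
        n_sig = 0
        n_tests = 0
        for _ in range(30):
            study = set(rng.choice(genes, size=30, replace=False))
            for r in go_enrichment(study, background, ann, toy_dag):
                n_tests += 1
                n_sig += r.q_bh < 0.05
        assert n_sig / max(n_tests, 1) < 0.05

    def test_study_must_be_subset(self, toy_dag, toy_annotations):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"y"}, toy_annotations, toy_dag)


class TestPermutationNull:
    def test_permutation_preserves_score_multiset(self):
        ts = {f"g{i}": float(i) for i in range(10)}
        kinds = {f"g{i}": "exon_gain" if i % 2 else "intron_retention" for i in range(10)}
        result = permute_ts_null(ts, kinds, n_perm=10, seed=0)
        # medians of both kinds in any permutation come from the same multiset
        assert set(result.observed_median) == {"exon_gain", "intron_retention"}
        assert all(len(v) == 10 for v in result.null_medians.values())

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        ts = {}
        kinds = {}
        for i in range(40):
            g = f"g{i}"
            if i < 20:
                kinds[g], ts[g] = "exon_gain", rng.uniform(0.6, 1.0)
            else:
                kinds[g], ts[g] = "other", rng.uniform(0.0, 0.4)
        result = permute_ts_null(ts, kinds, n_perm=999, seed=7)
        assert result.p_empirical["exon_gain"] < 0.01

    def test_direction_flip_for_depleted_kind(self):
        rng = np.random.default_rng(13)
        ts, kinds = {}, {}
        for i in range(40):
            g = f"g{i}"
            if i < 10:
                kinds[g], ts[g] = "intron_retention", rng.uniform(0.0, 0.2)
            else:
                kinds[g], ts[g] = "other", rng.uniform(0.5, 1.0)
        res = permute_ts_null(ts, kinds, n_perm=499, seed=3,
                              directions={"intron_retention": "less"})
        assert res.p_empirical["intron_retention"] < 0.01

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permute_ts_null({"a": 0.1, "b": 0.2}, {"a": "x"}, n_perm=0, seed=0)

    def test_empirical_p_uniform_under_null(self):
        # truly null fixture: scores independent of labels; over many replicate
        # seeds the empirical p is uniform on {1/(n+1), ..., 1}
        n_perm, n_rep = 99, 200
        pvals = []
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            ts = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(size=24))}
            kinds = {f"g{i}": ("exon_gain" if i < 8 else "other") for i in range(24)}
            res = permute_ts_null(ts, kinds, n_perm=n_perm, seed=seed)
            pvals.append(res.p_empirical["exon_gain"])
        stat = sps.kstest(pvals, "uniform").pvalue
        assert stat > 0.01


class TestEuclideanMatch:
    def test_exact_copies_matched_at_zero(self):
        profiles = {"h1": np.array([1.0, 2.0]), "h2": np.array([5.0, 5.0]),
                    "c1": np.array([1.0, 2.0]), "c2": np.array([5.0, 5.0])}
        pairs = euclidean_match(["h1", "h2"], ["c1", "c2"], profiles)
        got = {case: (ctrl, d) for case, ctrl, d in pairs.pairs}
        assert got == {"h1": ("c1", 0.0), "h2": ("c2", 0.0)}

    def test_competition_resolved_by_processing_order(self):
        # both cases closest to c1; the higher-expressed case wins it
        profiles = {"big": np.array([10.0, 10.0]), "small": np.array([9.0, 9.0]),
                    "c1": np.array([9.5, 9.5]), "c2": np.array([0.0, 0.0])}
        pairs = euclidean_match(["small", "big"], ["c1", "c2"], profiles)
        got = {case: ctrl for case, ctrl, _ in pairs.pairs}
        assert got == {"big": "c1", "small": "c2"}

    def test_greedy_replay_certificate_and_injectivity(self):
        rng = np.random.default_rng(14)
        cases = [f"h{i}" for i in range(15)]
        pool = [f"c{i}" for i in range(25)]
        profiles = {g: rng.uniform(0, 10, size=6) for g in cases + pool}
        pairs = euclidean_match(cases, pool, profiles)
        controls = [ctrl for _, ctrl, _ in pairs.pairs]
        assert len(set(controls)) == len(controls)  # injective
        used = set()
        for case, ctrl, dist in pairs.pairs:
            for alt in pool:
                if alt not in used:
                    alt_d = float(np.linalg.norm(profiles[case] - profiles[alt]))
                    assert dist <= alt_d + 1e-12
            used.add(ctrl)

    def test_pool_smaller_than_cases_rejected(self):
        profiles = {"a": np.zeros(2), "b": np.zeros(2), "c": np.zeros(2)}
        with pytest.raises(ValueError):
            euclidean_match(["a", "b"], ["c"], profiles)


class TestStratified:
    def _labels(self):
        records = []
        rng = np.random.default_rng(6)
        for i in range(200):
            g = f"g{i}"
            dbd = i < 60
            # confounded fixture: essentiality driven entirely by DBD status
            essential = dbd and rng.random() < 0.8
            high_ts = (dbd and rng.random() < 0.7) or (not dbd and rng.random() < 0.2)
            singleton = i % 2 == 0
            records += [(g, "dbd_domain", dbd), (g, "essential", essential),
                        (g, "high_ts", high_ts), (g, "singleton", singleton)]
        return GeneLabelTable.from_records(records)

    def test_counts_match_manual_subset(self):
        labels = self._labels()
        res = stratified_enrichment(labels, "high_ts", "essential",
                                    strata={"singleton": True})
        df = labels.frame
        sub = df[df["singleton"].astype(bool)]
        assert res.a == int((sub["high_ts"] & sub["essential"]).sum())
        assert res.a + res.b + res.c + res.d == len(sub)

    def test_empty_stratum_flagged(self):
        labels = GeneLabelTable.from_records(
            [("g1", "high_ts", True), ("g1", "essential", True),
             ("g1", "rare", False), ("g2", "high_ts", False),
             ("g2", "essential", False), ("g2", "rare", False)])
        res = stratified_enrichment(labels, "high_ts", "essential",
                                    strata={"rare": True})
        assert res.flagged and res.p_one_sided == 1.0

    def test_confounded_enrichment_vanishes_when_confounder_removed(self):
        labels = self._labels()
        naive = stratified_enrichment(labels, "high_ts", "essential")
        controlled = stratified_enrichment(labels, "high_ts", "essential",
                                           strata={"dbd_domain": False})
        assert naive.p_one_sided < 0.01
        assert controlled.p_one_sided > 0.05

    def test_unknown_flag_rejected(self):
        with pytest.raises(KeyError):
            stratified_enrichment(self._labels(), "high_ts", "nope")
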