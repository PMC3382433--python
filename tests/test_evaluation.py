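"""Jaccard scoring, AT5/BAT5, quartile ranking, prominent annotations,
variation of information, and count/size summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cliqueclust import (
    AnnotationCollection,
    Clustering,
    ClusterScore,
    InvalidInputError,
    OverlapError,
    at5,
    bat5,
    cluster_count_size_summary,
    jaccard,
    prominent_annotations,
    quartile_rank,
    score_cluster,
    variation_of_information,
)
from conftest import random_partition
from _oracles import best_category_match, entropy_vi, rank_quartiles

genes_st = st.sets(st.sampled_from([f"g{i}" for i in range(12)]))


class TestJaccard:
    def test_identical_sets_score_one(self):
        assert jaccard({"a", "b", "c"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert jaccard({"a", "b"}, {"c", "d"}) == 0.0

    def test_arithmetic_example(self):
        assert jaccard({"a", "b", "c", "d"}, {"a", "b", "e"}) == pytest.approx(0.4)

    def test_both_empty_scores_zero(self):
        assert jaccard(set(), set()) == 0.0

    @given(genes_st, genes_st)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        if a or b:
            assert (j == 1.0) == (a == b)


def _ann(cats, source="GO"):
    return AnnotationCollection(source=source, categories={k: frozenset(v) for k, v in cats.items()})


class TestScoreCluster:
    def test_exact_category_match_is_perfect(self):
        ann = _ann({"c1": {"a", "b", "c"}, "c2": {"x", "y"}})
        s = score_cluster({"a", "b", "c"}, ann)
        assert s.best_category == "c1" and s.jaccard == 1.0
        assert s.fp == 0 and s.fn == 0 and s.tp == 3

    def test_single_shared_gene_never_qualifies(self):
        ann = _ann({"c1": {"a", "x", "y"}, "c2": {"b", "z", "w"}})
        s = score_cluster({"a", "b", "q"}, ann)
        assert s.best_category is None and s.jaccard == 0.0

    def test_genes_outside_universe_are_ignored(self):
        ann = _ann({"c1": {"a", "b", "c"}})
        base = score_cluster({"a", "b", "c"}, ann)
        noisy = score_cluster({"a", "b", "c", "unknown1", "unknown2"}, ann)
        assert noisy.jaccard == base.jaccard == 1.0

    def test_fn_counts_genomewide_within_source(self):
        ann = _ann({"c1": {"a", "b", "c", "d", "e"}})
        s = score_cluster({"a", "b"}, ann)
        assert (s.tp, s.fp, s.fn) == (2, 0, 3)
        assert s.jaccard == pytest.approx(2 / 5)

    def test_best_across_two_collections(self):
        go = _ann({"go1": {"a", "b", "x"}}, source="GO")
        kegg = _ann({"k1": {"a", "b", "c"}}, source="KEGG")
        s = score_cluster({"a", "b", "c"}, go, kegg)
        assert s.best_category == "k1" and s.source == "KEGG"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_category_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(60)]
        cats = {
            f"cat{i:02d}": set(rng.choice(pool, size=rng.integers(3, 15), replace=False))
            for i in range(20)
        }
        ann = _ann(cats)
        cluster = set(rng.choice(pool, size=15, replace=False))
        s = score_cluster(cluster, ann)
        oj, oc = best_category_match(cluster, cats, ann.universe)
        assert s.jaccard == pytest.approx(oj)
        if oc is not None:
            assert s.best_category == oc
        # the reported score satisfies the TP/(TP+FP+FN) identity
        if s.best_category is not None:
            assert s.jaccard == pytest.approx(s.tp / (s.tp + s.fp + s.fn))
            assert s.tp >= 2


class TestAT5BAT5:
    def test_top_five_average(self):
        val, under = at5([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        assert val == pytest.approx(0.7) and not under

    def test_underfilled_bin_flagged(self):
        val, under = at5([0.6])
        assert val == pytest.approx(0.6) and under

    def test_empty_bin_is_absent(self):
        assert at5([]) == (None, True)

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(0)
        scores = list(rng.random(100))
        val, _ = at5(scores)
        assert val == pytest.approx(sum(sorted(scores)[-5:]) / 5)

    def test_at5_monotone_when_a_score_increases(self):
        rng = np.random.default_rng(1)
        scores = list(rng.random(20))
        base, _ = at5(scores)
        for i in range(len(scores)):
            bumped = list(scores)
            bumped[i] = min(1.0, bumped[i] + 0.3)
            assert at5(bumped)[0] >= base

    def test_bat5_is_max_with_parameter(self):
        assert bat5({"p1": 0.3, "p2": 0.5, "p3": 0.4}) == (0.5, "p2")
        assert bat5({"only": 0.7}) == (0.7, "only")

    def test_bat5_dominates_every_at5(self):
        rng = np.random.default_rng(2)
        table = {f"p{i}": float(rng.random()) for i in range(20)}
        best, param = bat5(table)
        assert best == pytest.approx(max(table.values()))
        assert all(best >= v for v in table.values())
        assert table[param] == best

    def test_bat5_empty_map_rejected(self):
        with pytest.raises(InvalidInputError):
            bat5({})


class TestQuartileRank:
    def test_four_methods_one_per_quartile(self):
        table = {
            "m1": {"small": 0.9}, "m2": {"small": 0.7},
            "m3": {"small": 0.5}, "m4": {"small": 0.3},
        }
        from cliqueclust.evaluation import SizeBins

        bins = SizeBins(edges=((3, 10),), names=("small",))
        df = quartile_rank(table, bins)
        assert list(df["method"]) == ["m1", "m2", "m3", "m4"]
        assert list(df["quartile_small"]) == [1, 2, 3, 4]

    def test_all_tied_methods_share_first_quartile(self):
        from cliqueclust.evaluation import SizeBins

        bins = SizeBins(edges=((3, 10),), names=("small",))
        table = {f"m{i}": {"small": 0.5} for i in range(6)}
        df = quartile_rank(table, bins)
        assert set(df["quartile_small"]) == {1}

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        methods = [f"m{i:02d}" for i in range(14)]
        table = {
            m: {b: float(rng.random()) for b in ("small", "medium", "large")}
            for m in methods
        }
        df = quartile_rank(table).set_index("method")
        for b in ("small", "medium", "large"):
            expected = rank_quartiles({m: table[m][b] for m in methods})
            for m in methods:
                assert df.loc[m, f"quartile_{b}"] == expected[m]

    def test_empty_bin_renders_zero_and_is_excluded_from_average(self):
        table = {
            "full": {"small": 0.8, "medium": 0.6, "large": 0.4},
            "partial": {"small": 0.9, "medium": 0.7, "large": None},
        }
        df = quartile_rank(table).set_index("method")
        assert df.loc["partial", "bat5_large"] == 0.0
        assert df.loc["partial", "quartile_large"] == ""
        # with M=2 methods, rank 1 -> ceil(4*1/2) = quartile 2, rank 2 -> 4
        assert df.loc["partial", "avg_quartile"] == pytest.approx(2.0)
        assert df.loc["full", "avg_quartile"] == pytest.approx(4.0)


class TestProminentAnnotations:
    def _score(self, cat, j, tp=2):
        fn = round(tp / j) - tp if j > 0 else 0
        return ClusterScore(
            cluster_id="c", size=5, jaccard=tp / (tp + fn), best_category=cat,
            tp=tp, fp=0, fn=fn,
        )

    def test_category_above_cutoff_selected_and_averaged(self):
        a = [self._score("catX", 0.4, tp=2)]  # jaccard 2/5 = 0.4
        b = [self._score("catY", 0.2, tp=2)]  # jaccard 0.2 < cutoff
        selected, means = prominent_annotations({"A": a, "B": b}, cutoff=0.25)
        assert selected == ["catX"]
        assert means["A"] == pytest.approx(0.4)
        assert means["B"] == 0.0

    def test_high_cutoff_selects_nothing(self):
        a = [self._score("catX", 0.4, tp=2)]
        selected, means = prominent_annotations({"A": a}, cutoff=0.9)
        assert selected == [] and means["A"] == 0.0

    def test_matches_filter_and_average_oracle(self):
        rng = np.random.default_rng(4)
        cats = [f"cat{i}" for i in range(10)]
        history = {}
        for m in ("A", "B", "C"):
            scores = []
            for _ in range(30):
                tp = int(rng.integers(2, 6))
                fn = int(rng.integers(0, 8))
                scores.append(
                    ClusterScore(
                        cluster_id="c", size=tp, jaccard=tp / (tp + fn),
                        best_category=str(rng.choice(cats)), tp=tp, fp=0, fn=fn,
                    )
                )
            history[m] = scores
        selected, means = prominent_annotations(history, cutoff=0.25)
        # oracle: exhaustive filter and average
        best = {}
        for m, scores in history.items():
            for s in scores:
                best[(m, s.best_category)] = max(
                    best.get((m, s.best_category), 0.0), s.jaccard
                )
        exp_selected = sorted(
            {c for (_, c), v in best.items() if v > 0.25}
        )
        assert selected == exp_selected
        for m in history:
            exp = sum(best.get((m, c), 0.0) for c in exp_selected) / len(exp_selected)
            assert means[m] == pytest.approx(exp)


def _clustering(parts, method="m"):
    return Clustering(method=method, clusters=[frozenset(p) for p in parts])


class TestVariationOfInformation:
    def test_identical_partitions_score_exactly_zero(self):
        c = _clustering([{"a", "b"}, {"c", "d", "e"}])
        assert variation_of_information(c, c) == 0.0

    def test_one_cluster_vs_singletons_is_log_n(self):
        a = _clustering([{"a", "b", "c", "d"}])
        b = _clustering([{"a"}, {"b"}, {"c"}, {"d"}])
        assert variation_of_information(a, b) == pytest.approx(math.log(4))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_entropy_oracle_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        a = _clustering(random_partition(genes, 4, rng), "a")
        b = _clustering(random_partition(genes, 5, rng), "b")
        vi = variation_of_information(a, b)
        la, lb = a.membership(), b.membership()
        assert vi == pytest.approx(entropy_vi(la, lb, genes), abs=1e-12)
        # cross-check against scikit-learn: H(A) = I(A;A), so
        # VI = I(A;A) + I(B;B) - 2 I(A;B)
        from sklearn.metrics import mutual_info_score

        va = [la[g] for g in genes]
        vb = [lb[g] for g in genes]
        expected = (
            mutual_info_score(va, va)
            + mutual_info_score(vb, vb)
            - 2 * mutual_info_score(va, vb)
        )
        assert vi == pytest.approx(expected, abs=1e-9)

    def test_overlapping_clusters_are_not_applicable(self):
        a = _clustering([{"a", "b"}, {"b", "c"}])
        b = _clustering([{"a"}, {"b"}, {"c"}])
        with pytest.raises(OverlapError):
            variation_of_information(a, b)
        with pytest.raises(OverlapError):
            variation_of_information(b, a)

    def test_evaluated_over_covered_intersection(self):
        a = _clustering([{"a", "b"}, {"c", "d"}])
        b = _clustering([{"a", "b"}, {"c", "d", "x", "y"}])
        # restricted to {a,b,c,d} the partitions coincide
        assert variation_of_information(a, b) == 0.0

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(25)]
        for _ in range(60):
            a = _clustering(random_partition(genes, 3, rng), "a")
            b = _clustering(random_partition(genes, 4, rng), "b")
            c = _clustering(random_partition(genes, 5, rng), "c")
            ab = variation_of_information(a, b)
            ba = variation_of_information(b, a)
            ac = variation_of_information(a, c)
            cb = variation_of_information(c, b)
            assert ab >= 0.0
            assert ab == pytest.approx(ba, abs=1e-12)
            assert ab <= ac + cb + 1e-9


class TestCountSizeSummary:
    def test_one_cluster_per_bin(self):
        c = _clustering([set(range(4)), set(range(12)), set(range(150))])
        df = cluster_count_size_summary({"m": c}).set_index("bin")
        assert list(df["n_clusters"]) == [1, 1, 1]

    def test_zero_cells_reported_explicitly(self):
        c = _clustering([set(range(4))])
        df = cluster_count_size_summary({"m": c}).set_index("bin")
        assert df.loc["large", "n_clusters"] == 0
        assert df.loc["large", "mean_size"] == 0.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(6)
        sizes = rng.integers(3, 300, size=50)
        clusters = [frozenset(f"g{i}_{j}" for j in range(s)) for i, s in enumerate(sizes)]
        df = cluster_count_size_summary({"m": Clustering(method="m", clusters=clusters)})
        df = df.set_index("bin")
        for name, lo, hi in (("small", 3, 10), ("medium", 11, 100), ("large", 101, 1000)):
            in_bin = [s for s in sizes if lo <= s <= hi]
            assert df.loc[name, "n_clusters"] == len(in_bin)
            if in_bin:
                assert df.loc[name, "mean_size"] == pytest.approx(
                    sum(in_bin) / len(in_bin), abs=1e-4
                )
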