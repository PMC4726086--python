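import numpy as np
import pytest
from scipy import stats

from bacnet.io_formats import AnnotationSet, ExpressionMatrix, GoDag
from bacnet.network import remove_self_loops
from bacnet.validation import (
    SemanticSimilarity,
    compare_with_random,
    edge_expression_pcc,
    go_term_similarity,
    protein_functional_similarity,
    transcription_pcc_validation,
    wilcoxon_rank_sum,
)


def simple_dag():
    """root <- mid <- leaf plus a second leaf under the root."""
    return GoDag(
        terms={"root", "mid", "leafA", "leafB"},
        edges={
            "mid": [("root", "is_a")],
            "leafA": [("root", "is_a")],
            "leafB": [("root", "is_a")],
        },
        namespace={t: "BP" for t in ("root", "mid", "leafA", "leafB")},
    )


class TestWangSimilarity:
    def test_identical_terms(self):
        assert go_term_similarity("leafA", "leafA", simple_dag()) == 1.0

    def test_two_leaves_sharing_only_the_root(self):
        # S-values {self: 1, root: 0.8}; sim = 1.6 / 3.6
        sim = go_term_similarity("leafA", "leafB", simple_dag())
        assert sim == pytest.approx(0.4444, abs=1e-4)

    def test_part_of_weight(self):
        dag = GoDag(
            terms={"root", "p"},
            edges={"p": [("root", "part_of")]},
            namespace={"root": "BP", "p": "BP"},
        )
        calc = SemanticSimilarity(dag)
        assert calc.s_values("p") == {"p": 1.0, "root": 0.6}

    def test_disjoint_components_have_zero_similarity(self):
        dag = GoDag(
            terms={"r1", "r2", "a", "b"},
            edges={"a": [("r1", "is_a")], "b": [("r2", "is_a")]},
            namespace={t: "BP" for t in ("r1", "r2", "a", "b")},
        )
        assert go_term_similarity("a", "b", dag) == 0.0

    def test_cross_namespace_rejected(self):
        dag = GoDag(
            terms={"a", "b"},
            edges={},
            namespace={"a": "BP", "b": "MF"},
        )
        with pytest.raises(ValueError):
            go_term_similarity("a", "b", dag)

    def test_symmetry_and_monotone_decay_along_chain(self):
        # chain t0 <- t1 <- t2 <- t3; sim(t0, tk) decreases with k
        terms = [f"t{i}" for i in range(4)]
        dag = GoDag(
            terms=set(terms),
            edges={terms[i]: [(terms[i - 1], "is_a")] for i in range(1, 4)},
            namespace={t: "BP" for t in terms},
        )
        calc = SemanticSimilarity(dag)
        sims = [calc.term_similarity("t3", t) for t in ("t3", "t2", "t1", "t0")]
        assert sims[0] == 1.0
        assert all(a > b for a, b in zip(sims, sims[1:]))
        assert calc.term_similarity("t0", "t3") == calc.term_similarity("t3", "t0")


class TestProteinSimilarity:
    def test_identical_term_sets(self):
        ann = AnnotationSet(go={"p1": {"leafA"}, "p2": {"leafA"}})
        sim = protein_functional_similarity("p1", "p2", ann, simple_dag())
        assert sim == pytest.approx(1.0)

    def test_best_match_average_hand_value(self):
        # A:{t1}, B:{t1, t2}, sim(t1, t2) known -> BMA = (1 + (1+s)/2) / 2
        dag = simple_dag()
        s = go_term_similarity("leafA", "leafB", dag)
        ann = AnnotationSet(go={"A": {"leafA"}, "B": {"leafA", "leafB"}})
        sim = protein_functional_similarity("A", "B", ann, dag)
        assert sim == pytest.approx((1 + (1 + s) / 2) / 2)
        assert sim == pytest.approx(0.85, abs=0.012)

    def test_disjoint_namespaces_skipped(self):
        dag = GoDag(
            terms={"b", "m"},
            edges={},
            namespace={"b": "BP", "m": "MF"},
        )
        ann = AnnotationSet(go={"p1": {"b"}, "p2": {"m"}})
        assert protein_functional_similarity("p1", "p2", ann, dag) is None


class TestWilcoxon:
    def test_exact_small_sample(self):
        report = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert report.method == "exact"
        assert report.p_value == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_one(self):
        report = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert report.p_value == pytest.approx(1.0)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 1, 50)
        y = rng.normal(0, 1, 50)
        report = wilcoxon_rank_sum(x, y, alternative="greater")
        assert report.p_value < 1e-6

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            for alt in ("two-sided", "greater", "less"):
                mine = wilcoxon_rank_sum(x, y, alternative=alt)
                ref = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = wilcoxon_rank_sum(x, y)
            assert exact.method == "exact"
            from bacnet.validation import _normal_rank_sum_p, _rank_sum_statistic

            w = _rank_sum_statistic(np.asarray(x), np.asarray(y))
            approx = _normal_rank_sum_p(w, np.asarray(x), np.asarray(y),
                                        "two-sided")
            assert abs(exact.p_value - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestExpressionPcc:
    def test_affine_profiles_fully_correlated(self):
        expr = ExpressionMatrix(
            rpkm={"a": np.array([1.0, 2.0, 3.0]),
                  "b": np.array([3.0, 5.0, 7.0])},
            time_labels=["t1", "t2", "t3"],
        )
        assert edge_expression_pcc("a", "b", expr) == pytest.approx(1.0)

    def test_reversed_profiles_anticorrelated(self):
        expr = ExpressionMatrix(
            rpkm={"a": np.array([1.0, 2.0, 3.0]),
                  "b": np.array([3.0, 2.0, 1.0])},
            time_labels=["t1", "t2", "t3"],
        )
        assert edge_expression_pcc("a", "b", expr) == pytest.approx(-1.0)

    def test_zero_variance_profile_skipped(self):
        expr = ExpressionMatrix(
            rpkm={"a": np.array([1.0, 1.0, 1.0]),
                  "b": np.array([3.0, 2.0, 1.0])},
            time_labels=["t1", "t2", "t3"],
        )
        assert edge_expression_pcc("a", "b", expr) is None

    def test_too_few_time_points_rejected(self, small_world):
        net, _ = remove_self_loops(small_world.truth_network)
        expr = ExpressionMatrix(
            rpkm={p: v[:2] for p, v in small_world.expression.rpkm.items()},
            time_labels=small_world.expression.time_labels[:2],
        )
        with pytest.raises(ValueError):
            transcription_pcc_validation(net, expr)


class TestPlantedSignal:
    def test_go_and_pcc_significant_on_signal_world(self, small_world):
        net, _ = remove_self_loops(small_world.truth_network)
        go_report = compare_with_random(
            net, small_world.annotations, small_world.go_dag,
            n_random=10, seed=5,
        )
        pcc_report = transcription_pcc_validation(
            net, small_world.expression, n_random=10, seed=6
        )
        assert go_report.p_value < 0.01
        assert pcc_report.p_value < 0.01

    def test_seeded_comparison_is_deterministic(self, small_world):
        net, _ = remove_self_loops(small_world.truth_network)
        r1 = transcription_pcc_validation(net, small_world.expression,
                                          n_random=5, seed=3)
        r2 = transcription_pcc_validation(net, small_world.expression,
                                          n_random=5, seed=3)
        assert r1 == r2
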