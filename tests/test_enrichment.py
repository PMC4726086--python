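import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bacnet.enrichment import (
    annotate_uncharacterized,
    cog_heatmap,
    fisher_enrichment,
    functional_entropy,
)
from bacnet.io_formats import AnnotationSet, EdgeRecord
from bacnet.network import PPINetwork
from conftest import net_from_pairs


class TestHeatmap:
    def toy(self):
        """3 proteins in class I, 3 in class J; 5 edges, 4 of them I-J."""
        pairs = [("i1", "j1"), ("i2", "j2"), ("i3", "j1"), ("i1", "j3"),
                 ("i1", "i2")]
        annotations = AnnotationSet(
            cog={p: ["I"] for p in ("i1", "i2", "i3")}
            | {p: ["J"] for p in ("j1", "j2", "j3")}
        )
        return net_from_pairs(pairs), annotations

    def test_toy_z_score(self):
        net, annotations = self.toy()
        hm = cog_heatmap(net, annotations)
        assert hm.n == 6 and hm.N == 5
        # P_IJ = 3*3/15 = 0.6, expected 3, Z = 1/sqrt(1.2)
        assert hm.zscore("I", "J") == pytest.approx(0.9129, abs=1e-4)
        i = hm.categories.index("I")
        j = hm.categories.index("J")
        assert hm.expected[i, j] == pytest.approx(3.0)

    def test_single_class_degenerate(self):
        # all proteins in one class: A_JJ = N and P_JJ = 1, so the Z-score
        # is undefined and must be reported as missing, not infinity
        net = net_from_pairs([("a", "b"), ("b", "c")])
        annotations = AnnotationSet(cog={p: ["J"] for p in "abc"})
        hm = cog_heatmap(net, annotations)
        assert hm.counts[0, 0] == hm.N
        assert math.isnan(hm.zscore("J", "J"))

    def test_partial_single_class_z_non_negative(self):
        # two classes but every edge within class J: Z_JJ must be positive
        pairs = [("a", "b"), ("b", "c"), ("a", "c")]
        annotations = AnnotationSet(
            cog={"a": ["J"], "b": ["J"], "c": ["J"], "d": ["K"], "e": ["K"]}
        )
        net = net_from_pairs(pairs)
        net.graph.add_node("d")
        net.graph.add_node("e")
        hm = cog_heatmap(net, annotations)
        assert hm.zscore("J", "J") > 0

    def test_null_expectation_gives_zero_z(self):
        # construct A_ij = N * P_ij exactly: 2+2 proteins, all 4 cross edges
        # P_IJ = 4/6; with N=6 edges total that expectation is 4
        pairs = [("i1", "j1"), ("i1", "j2"), ("i2", "j1"), ("i2", "j2"),
                 ("i1", "i2"), ("j1", "j2")]
        annotations = AnnotationSet(
            cog={"i1": ["I"], "i2": ["I"], "j1": ["J"], "j2": ["J"]}
        )
        hm = cog_heatmap(net_from_pairs(pairs), annotations)
        assert hm.zscore("I", "J") == pytest.approx(0.0, abs=1e-12)

    def test_single_label_edge_counts_conserved(self, small_world):
        """With single-label annotations, every edge lands in exactly one
        category combination, so the A matrix totals the edge count."""
        world = small_world
        single = AnnotationSet(
            cog={p: cats[:1] for p, cats in world.annotations.cog.items()}
        )
        from bacnet.network import remove_self_loops

        net, _ = remove_self_loops(world.truth_network)
        hm = cog_heatmap(net, single)
        total = np.sum(np.triu(hm.counts))
        assert total == hm.N

    def test_z_symmetric_and_label_permutation_invariant(self, small_world):
        from bacnet.network import remove_self_loops

        world = small_world
        net, _ = remove_self_loops(world.truth_network)
        hm = cog_heatmap(net, world.annotations)
        assert np.allclose(hm.z, hm.z.T, equal_nan=True)

        mapping = {p: f"renamed_{p}" for p in net.nodes}
        renamed = PPINetwork(
            EdgeRecord(mapping[a], mapping[b]) for a, b in net.edges
        )
        renamed_ann = AnnotationSet(
            cog={mapping.get(p, p): c for p, c in world.annotations.cog.items()
                 if p in mapping}
        )
        hm2 = cog_heatmap(renamed, renamed_ann)
        assert hm2.categories == hm.categories
        assert np.allclose(hm.z, hm2.z, equal_nan=True)


def hypergeom_tail(k_obs, n_set, k_background, n_background):
    """P(X >= k_obs), X hypergeometric — enumeration oracle."""
    total = math.comb(n_background, n_set)
    acc = 0
    for k in range(k_obs, min(n_set, k_background) + 1):
        acc += math.comb(k_background, k) * math.comb(
            n_background - k_background, n_set - k
        )
    return acc / total


class TestFisher:
    def test_small_table_against_enumeration(self):
        annotations = AnnotationSet(
            cog={f"g{i}": ["G"] for i in range(10)}
            | {f"o{i}": ["K"] for i in range(90)}
        )
        background = set(annotations.cog)
        member_set = {"g0", "g1", "g2", "g3", "o0"}
        res = {r.category: r for r in
               fisher_enrichment(member_set, background, annotations)}
        expected = hypergeom_tail(4, 5, 10, 100)
        assert res["G"].p_value == pytest.approx(expected, rel=1e-9)
        assert res["G"].p_value == pytest.approx(2.5438e-4, rel=1e-3)
        assert res["G"].enriched

    def test_depleted_category_not_enriched(self):
        annotations = AnnotationSet(
            cog={f"a{i}": ["G"] for i in range(50)}
            | {f"b{i}": ["K"] for i in range(50)}
        )
        member_set = {f"b{i}" for i in range(5)}
        res = {r.category: r for r in
               fisher_enrichment(member_set, set(annotations.cog), annotations)}
        assert res["G"].p_value >= 0.5
        assert not res["G"].enriched

    def test_member_set_equal_to_background_never_enriched(self):
        annotations = AnnotationSet(cog={f"p{i}": ["G"] for i in range(10)})
        background = set(annotations.cog)
        res = fisher_enrichment(background, background, annotations)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"a"}, AnnotationSet())

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_background = int(rng.integers(10, 200))
            k_background = int(rng.integers(1, n_background))
            n_set = int(rng.integers(1, min(20, n_background)))
            cog = {}
            ids = [f"p{i}" for i in range(n_background)]
            for i, pid in enumerate(ids):
                cog[pid] = ["G"] if i < k_background else ["K"]
            member = set(rng.choice(ids, size=n_set, replace=False).tolist())
            res = {r.category: r
                   for r in fisher_enrichment(member, set(ids),
                                              AnnotationSet(cog=cog))}
            k_obs = sum(1 for p in member if cog[p] == ["G"])
            assert res["G"].p_value == pytest.approx(
                hypergeom_tail(k_obs, n_set, k_background, n_background),
                rel=1e-9,
            )


class TestEntropy:
    def test_homogeneous_complex_is_zero(self):
        ann = AnnotationSet(cog={f"p{i}": ["J"] for i in range(4)})
        assert functional_entropy([f"p{i}" for i in range(4)], ann).entropy == 0.0

    def test_even_split_is_one_bit(self):
        ann = AnnotationSet(
            cog={"p0": ["J"], "p1": ["J"], "p2": ["K"], "p3": ["K"]}
        )
        ce = functional_entropy(["p0", "p1", "p2", "p3"], ann)
        assert ce.entropy == pytest.approx(1.0)

    def test_uniform_over_three(self):
        ann = AnnotationSet(cog={"p0": ["J"], "p1": ["K"], "p2": ["L"]})
        ce = functional_entropy(["p0", "p1", "p2"], ann)
        assert ce.entropy == pytest.approx(math.log2(3))

    def test_unannotated_complex_flagged(self):
        ce = functional_entropy(["p0", "p1"], AnnotationSet())
        assert ce.entropy == 0.0 and ce.all_unknown

    def test_primary_category_only(self):
        ann = AnnotationSet(cog={"p0": ["J", "K"], "p1": ["J"]})
        ce = functional_entropy(["p0", "p1"], ann)
        assert ce.category_counts == {"J": 2}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=1,
                    max_size=40))
    def test_entropy_bounded_and_maximal_only_when_uniform(self, labels):
        letters = "JKLMNOPQTC"
        ann = AnnotationSet(
            cog={f"p{i}": [letters[lab]] for i, lab in enumerate(labels)}
        )
        members = [f"p{i}" for i in range(len(labels))]
        ce = functional_entropy(members, ann)
        c = len(set(labels))
        assert 0.0 <= ce.entropy <= math.log2(c) + 1e-12
        counts = [labels.count(x) for x in set(labels)]
        if len(set(counts)) == 1:
            assert ce.entropy == pytest.approx(math.log2(c))
        else:
            assert ce.entropy < math.log2(c)


class TestAnnotateUncharacterized:
    def _world(self):
        cog = {f"j{i}": ["J"] for i in range(4)}
        cog.update({f"k{i}": ["K"] for i in range(40)})
        annotations = AnnotationSet(cog=cog)
        background = set(cog) | {"u1", "u2"}
        return annotations, background

    def test_enriched_category_assigned_to_unknown_member(self):
        annotations, background = self._world()
        assigned = annotate_uncharacterized(
            [[f"j{i}" for i in range(4)] + ["u1"]], annotations, background
        )
        assert assigned == {"u1": "J"}

    def test_no_enrichment_no_assignment(self):
        annotations, background = self._world()
        # a complex drawn proportionally from the background
        members = ["j0", "k0", "k1", "k2", "u1"]
        assigned = annotate_uncharacterized(
            [members], annotations, background, alpha=0.001
        )
        assert assigned == {}

    def test_smallest_p_wins_across_complexes(self):
        annotations, background = self._world()
        complexes = [
            [f"j{i}" for i in range(4)] + ["u1"],        # strong J enrichment
            ["j0", "k0", "k1", "k2", "k3", "u1"],         # weaker K signal
        ]
        assigned = annotate_uncharacterized(complexes, annotations, background)
        assert assigned["u1"] == "J"
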