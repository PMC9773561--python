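"""Emotional entropy, triad taxonomy, censuses, and ordered triad counts."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emonet.affect_metrics import (
    SIGNATURES,
    classify_triad,
    emotional_entropy,
    ordered_triad_counts,
    triad_census,
    triad_signature,
    triangle_list,
)

from conftest import random_labeled_graph

POS, NEG, NEU = "positive", "negative", "neutral"
labels_st = st.lists(st.sampled_from([POS, NEG, NEU]), min_size=2, max_size=12)


class TestEmotionalEntropy:
    def test_two_scattered_switches_give_one_bit(self):
        # labels of {sad, sick, fine, great, normal}
        rec = emotional_entropy([NEG, NEG, POS, POS, NEU])
        assert rec.indicator == (0, 1, 0, 1)
        assert rec.h == pytest.approx(1.0)

    def test_constant_switching_gives_zero(self):
        # labels of {great, sad, fine, sick, normal}
        rec = emotional_entropy([POS, NEG, POS, NEG, NEU])
        assert rec.indicator == (1, 1, 1, 1)
        assert rec.h == 0.0

    def test_uniform_labels_give_zero(self):
        assert emotional_entropy([NEU] * 7).h == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="no transitions"):
            emotional_entropy([POS])

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="invalid valence"):
            emotional_entropy([POS, "angry"])

    @given(labels_st)
    @settings(max_examples=100)
    def test_bounded_in_unit_interval(self, seq):
        assert 0.0 <= emotional_entropy(seq).h <= 1.0

    @given(labels_st)
    @settings(max_examples=100)
    def test_invariant_under_polarity_flip(self, seq):
        flip = {POS: NEG, NEG: POS, NEU: NEU}
        assert emotional_entropy(seq).h == pytest.approx(
            emotional_entropy([flip[x] for x in seq]).h
        )

    def test_probabilities_sum_to_one(self):
        rec = emotional_entropy([POS, NEG, NEG, NEU, NEU, POS])
        assert rec.p_same + rec.p_diff == pytest.approx(1.0)


class TestTriadTaxonomy:
    # all 10 unordered signatures and their classification
    TAXONOMY = {
        (POS, POS, POS): "coherent",
        (POS, POS, NEG): "incoherent",
        (POS, POS, NEU): "coherent",
        (POS, NEG, NEG): "incoherent",
        (POS, NEG, NEU): "incoherent",
        (POS, NEU, NEU): "coherent",
        (NEG, NEG, NEG): "coherent",
        (NEG, NEG, NEU): "coherent",
        (NEG, NEU, NEU): "coherent",
        (NEU, NEU, NEU): "coherent",
    }

    @pytest.mark.parametrize("labels,expected", sorted(TAXONOMY.items()))
    def test_full_taxonomy(self, labels, expected):
        for perm in itertools.permutations(labels):
            assert classify_triad(perm) == expected

    def test_incoherent_iff_mixed_polarity(self):
        for labels in itertools.product([POS, NEG, NEU], repeat=3):
            expected = "incoherent" if POS in labels and NEG in labels else "coherent"
            assert classify_triad(labels) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_triad([POS, POS])
        with pytest.raises(ValueError):
            classify_triad([POS, POS, "meh"])

    def test_signatures_cover_all_multisets(self):
        seen = {triad_signature(l)
                for l in itertools.product([POS, NEG, NEU], repeat=3)}
        assert seen == set(SIGNATURES)
        assert len(SIGNATURES) == 10


def census_oracle(g: nx.Graph):
    """Exhaustive triple-loop census, independent of the implementation."""
    nodes = list(g.nodes)
    counts, inc = Counter(), 0
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            labs = [g.nodes[x]["sentiment_label"] for x in (a, b, c)]
            counts[triad_signature(labs)] += 1
            if POS in labs and NEG in labs:
                inc += 1
    return counts, inc


class TestTriadCensus:
    def test_single_positive_triangle(self):
        g = nx.complete_graph(3)
        nx.set_node_attributes(g, {i: POS for i in g.nodes}, "sentiment_label")
        cen = triad_census(g)
        assert cen.counts["+++"] == 1 and cen.c == 0.0

    def test_single_mixed_triangle(self):
        g = nx.complete_graph(3)
        nx.set_node_attributes(g, {0: POS, 1: NEG, 2: NEU}, "sentiment_label")
        cen = triad_census(g)
        assert cen.counts["+-n"] == 1 and cen.c == 1.0

    def test_triangle_free_graph_has_undefined_c(self):
        g = nx.path_graph(4)
        nx.set_node_attributes(g, {i: NEU for i in g.nodes}, "sentiment_label")
        cen = triad_census(g)
        assert cen.c is None and cen.n_triangles == 0

    def test_unlabeled_node_in_triangle_is_named(self):
        g = nx.complete_graph(3)
        nx.set_node_attributes(g, {0: POS, 1: NEG}, "sentiment_label")
        with pytest.raises(ValueError, match="2"):
            triad_census(g)

    def test_shared_edge_triangles(self, labeled_triangle_graph):
        cen = triad_census(labeled_triangle_graph)
        assert cen.n_triangles == 2
        assert cen.counts["+++"] == 1 and cen.counts["++-"] == 1
        assert cen.c == pytest.approx(0.5)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = random_labeled_graph(rng)
            cen = triad_census(g)
            oracle_counts, oracle_inc = census_oracle(g)
            assert {k: v for k, v in cen.counts.items() if v} == dict(oracle_counts)
            assert cen.n_incoherent == oracle_inc
            assert sum(cen.counts.values()) == len(triangle_list(g))

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(13)
        flip = {POS: NEG, NEG: POS, NEU: NEU}
        for _ in range(10):
            g = random_labeled_graph(rng)
            c1 = triad_census(g).c
            nx.set_node_attributes(
                g, {n: flip[g.nodes[n]["sentiment_label"]] for n in g.nodes},
                "sentiment_label")
            assert triad_census(g).c == c1

    def test_all_neutral_forces_zero_complexity(self):
        g = nx.complete_graph(6)
        nx.set_node_attributes(g, {i: NEU for i in g.nodes}, "sentiment_label")
        assert triad_census(g).c == 0.0

    def test_census_conservation(self):
        rng = np.random.default_rng(17)
        g = random_labeled_graph(rng, n_max=10, p=0.5)
        cen = triad_census(g)
        assert cen.n_coherent + cen.n_incoherent == cen.n_triangles
        if cen.n_triangles:
            assert cen.c == pytest.approx(1 - cen.n_coherent / cen.n_triangles)


class TestOrderedTriads:
    def test_alternating_sequence(self):
        counts = ordered_triad_counts([POS, NEG, POS, NEG])
        assert counts == {("+", "-", "+"): 1, ("-", "+", "-"): 1}

    def test_too_short_gives_empty_counts(self):
        assert ordered_triad_counts([POS, POS]) == Counter()

    @pytest.mark.parametrize("lab,sig", [(POS, "+"), (NEG, "-"), (NEU, "n")])
    def test_constant_sequence(self, lab, sig):
        counts = ordered_triad_counts([lab] * 9)
        assert counts == {(sig, sig, sig): 7}

    @given(st.lists(st.sampled_from([POS, NEG, NEU]), min_size=3, max_size=12))
    @settings(max_examples=100)
    def test_matches_sliding_window_oracle(self, seq):
        sign = {POS: "+", NEG: "-", NEU: "n"}
        oracle = Counter(
            (sign[seq[i]], sign[seq[i + 1]], sign[seq[i + 2]])
            for i in range(len(seq) - 2)
        )
        assert ordered_triad_counts(seq) == oracle
        assert sum(oracle.values()) == len(seq) - 2
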