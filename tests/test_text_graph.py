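"""Corpus loading, co-occurrence networks, closeness, homophily, frames."""

import itertools

import networkx as nx
import numpy as np
import pytest

from emonet.text_graph import (
    ALL_SENTENCES,
    LAST_SENTENCES,
    build_cooccurrence_network,
    closeness,
    corpus_from_texts,
    edge_valence_homophily,
    export_network,
    last_words,
    load_corpus,
    semantic_frame,
    tokenize_sentences,
)

from conftest import random_labeled_graph


def bfs_closeness_oracle(g: nx.Graph) -> dict:
    """Independent all-pairs BFS implementation of (N-1)/sum(d)."""
    out = {}
    for comp in nx.connected_components(g):
        comp = set(comp)
        for u in comp:
            if len(comp) == 1:
                out[u] = 0.0
                continue
            dist = {u: 0}
            frontier = [u]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for x in frontier:
                    for y in g.neighbors(x):
                        if y not in dist:
                            dist[y] = d
                            nxt.append(y)
                frontier = nxt
            out[u] = (len(comp) - 1) / sum(dist.values())
    return out


class TestTokenizationAndLoading:
    def test_two_sentence_note_lowercased(self):
        assert tokenize_sentences("I am tired. Goodbye all.") == [
            ["i", "am", "tired"], ["goodbye", "all"],
        ]

    def test_apostrophes_kept_inside_words(self):
        assert tokenize_sentences("I can't stay!") == [["i", "can't", "stay"]]

    def test_short_notes_dropped(self):
        corpus = corpus_from_texts(
            [("a", "One sentence only"), ("b", "Two. Sentences."),
             ("c", "Also. Two here.")]
        )
        assert len(corpus) == 2
        assert {n.note_id for n in corpus.notes} == {"b", "c"}

    def test_bulk_filter_keeps_multi_sentence_notes(self):
        records = [(f"n{i}", "Stay with me. Please do.") for i in range(139)]
        records += [(f"s{i}", "Goodbye") for i in range(4)]
        assert len(corpus_from_texts(records)) == 139

    def test_empty_after_filtering_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            corpus_from_texts([("a", "too short")])

    def test_load_from_dir_and_csv(self, tmp_path):
        (tmp_path / "x.txt").write_text("I am tired. Goodbye all.")
        (tmp_path / "y.txt").write_text("So long. Farewell friends.")
        corpus = load_corpus(tmp_path)
        assert len(corpus) == 2
        csv = tmp_path / "c.csv"
        csv.write_text('note_id,text\nn1,"I am tired. Goodbye all."\n')
        assert len(load_corpus(csv)) == 1


class TestCooccurrenceNetwork:
    def test_single_sentence_bigrams(self):
        corpus = corpus_from_texts([("a", "i love you. truly so.")])
        g = build_cooccurrence_network(corpus)
        assert set(map(frozenset, g.edges)) >= {
            frozenset({"i", "love"}), frozenset({"love", "you"})}

    def test_repeated_bigram_accumulates_weight(self):
        records = [(f"n{i}", "pain hurt deeply. nothing else matters.")
                   for i in range(5)]
        g = build_cooccurrence_network(corpus_from_texts(records))
        assert g["pain"]["hurt"]["weight"] == 5
        assert g.number_of_edges() == len(set(map(frozenset, g.edges)))

    def test_adjacent_repetition_yields_no_self_loop(self):
        corpus = corpus_from_texts([("a", "very very sad. so it goes.")])
        g = build_cooccurrence_network(corpus)
        assert not g.has_edge("very", "very")
        assert g.has_edge("very", "sad")

    def test_every_edge_is_witnessed_by_an_adjacent_pair(self):
        corpus = corpus_from_texts(
            [("a", "i love you so. goodbye my dear friend."),
             ("b", "you love life. hold on to hope.")]
        )
        g = build_cooccurrence_network(corpus)
        witnessed = set()
        for sent in corpus.sentences(ALL_SENTENCES):
            witnessed |= {frozenset(p) for p in zip(sent, sent[1:]) if p[0] != p[1]}
        assert set(map(frozenset, g.edges)) == witnessed

    def test_last_scope_vocabulary_is_subset_of_full_scope(self):
        corpus = corpus_from_texts(
            [("a", "i love you so. goodbye my dear friend."),
             ("b", "you love life. hold on to hope.")]
        )
        g_all = build_cooccurrence_network(corpus, ALL_SENTENCES)
        g_last = build_cooccurrence_network(corpus, LAST_SENTENCES)
        assert set(g_last.nodes) <= set(g_all.nodes)


class TestCloseness:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        c = closeness(g)
        assert c["b"] == pytest.approx(1.0)
        assert c["a"] == c["c"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_complete_graph_all_ones(self, n):
        assert all(v == pytest.approx(1.0)
                   for v in closeness(nx.complete_graph(n)).values())

    def test_singleton_component_gets_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("lonely")
        c = closeness(g)
        assert c["lonely"] == 0.0
        assert c["a"] == pytest.approx(1.0)

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_labeled_graph(rng)
            ours = closeness(g)
            oracle = bfs_closeness_oracle(g)
            for n in g.nodes:
                assert ours[n] == pytest.approx(oracle[n])


def tau_b_oracle(pairs):
    """O(n^2) concordant/discordant Kendall tau-b on (x, y) pairs."""
    n = len(pairs)
    conc = disc = tx = ty = 0
    for (x1, y1), (x2, y2) in itertools.combinations(pairs, 2):
        dx, dy = x1 - x2, y1 - y2
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    denom = ((conc + disc + tx) * (conc + disc + ty)) ** 0.5
    return (conc - disc) / denom


class TestHomophily:
    @staticmethod
    def _graph(edges, labels):
        g = nx.Graph()
        g.add_edges_from(edges)
        nx.set_node_attributes(g, labels, "sentiment_label")
        return g

    def test_perfect_concordance(self):
        g = self._graph(
            [("a", "b"), ("c", "d"), ("e", "f")],
            {"a": "positive", "b": "positive", "c": "negative", "d": "negative",
             "e": "neutral", "f": "neutral"},
        )
        assert edge_valence_homophily(g).kendall_tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        g = self._graph(
            [("a", "b"), ("c", "d")],
            {"a": "positive", "b": "negative", "c": "negative", "d": "positive"},
        )
        assert edge_valence_homophily(g).kendall_tau == pytest.approx(-1.0)

    def test_all_same_label_is_flagged_undefined(self):
        g = self._graph([("a", "b"), ("b", "c")],
                        {x: "positive" for x in "abc"})
        res = edge_valence_homophily(g)
        assert not res.defined

    def test_too_few_edges_rejected(self):
        g = self._graph([("a", "b")], {"a": "positive", "b": "negative"})
        with pytest.raises(ValueError):
            edge_valence_homophily(g)

    def test_matches_quadratic_tau_oracle(self):
        rng = np.random.default_rng(7)
        ord_map = {"negative": -1, "neutral": 0, "positive": 1}
        for _ in range(20):
            g = random_labeled_graph(rng)
            if g.number_of_edges() < 2:
                continue
            res = edge_valence_homophily(g)
            if not res.defined:
                continue
            pairs = []
            for u, v in g.edges:
                lu = ord_map[g.nodes[u]["sentiment_label"]]
                lv = ord_map[g.nodes[v]["sentiment_label"]]
                pairs += [(lu, lv), (lv, lu)]
            assert res.kendall_tau == pytest.approx(tau_b_oracle(pairs))


class TestLastWordsAndFrames:
    def test_stopwords_and_placeholders_excluded(self):
        corpus = corpus_from_texts(
            [("a", "I will miss this place. Goodbye to my dear name_anna.")]
        )
        assert last_words(corpus) == {"goodbye", "dear"}

    def test_all_stopword_final_sentence_contributes_nothing(self):
        corpus = corpus_from_texts([("a", "peace is near. to my own.")])
        assert last_words(corpus) == set()

    def test_set_semantics_across_notes(self):
        corpus = corpus_from_texts(
            [("a", "hold on. find peace."), ("b", "stay well. find peace.")]
        )
        assert last_words(corpus) == {"find", "peace"}

    def test_star_frame_returns_all_leaves(self, tiny_lexicon):
        g = nx.star_graph(["sad", "fine", "great", "table"])  # sad is center
        frame = semantic_frame(g, "sad", tiny_lexicon)
        assert set(frame) == {"fine", "great", "table"}
        assert frame["fine"]["sentiment_label"] == "positive"
        assert frame["fine"]["emotions"] == {"joy", "trust"}

    def test_isolated_node_has_empty_frame(self, tiny_lexicon):
        g = nx.Graph()
        g.add_node("sad")
        assert semantic_frame(g, "sad", tiny_lexicon) == {}

    def test_missing_word_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            semantic_frame(nx.path_graph(["a", "b"]), "ghost")

    def test_frame_matches_edge_scan(self, tiny_lexicon):
        rng = np.random.default_rng(3)
        g = random_labeled_graph(rng)
        node = list(g.nodes)[0]
        frame = semantic_frame(g, node)
        scan = {v for u, v in g.edges if u == node} | {
            u for u, v in g.edges if v == node}
        assert set(frame) == scan


def test_export_writes_edge_and_node_tables(tmp_path, tiny_lexicon):
    corpus = corpus_from_texts([("a", "i love you. goodbye sad world.")])
    g = build_cooccurrence_network(corpus, lexicon=tiny_lexicon)
    export_network(g, tmp_path / "edges.tsv", tmp_path / "nodes.csv")
    import pandas as pd

    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    nodes = pd.read_csv(tmp_path / "nodes.csv")
    assert len(edges) == g.number_of_edges()
    assert set(nodes["word"]) == set(g.nodes)
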