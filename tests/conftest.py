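"""Shared fixtures: tiny hand-auditable lexicons, corpora, and graphs."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from emonet.lexicon import AffectLexicon, EmotionalDictionary

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_lexicon() -> AffectLexicon:
    """8 words with scores 1..8: quartile labeling makes the 2 lowest
    negative, the 2 highest positive, the middle 4 neutral."""
    scores = {
        "sad": 1.0, "sick": 2.0,          # negative
        "normal": 3.0, "table": 4.0,      # neutral
        "the": 5.0, "good": 6.0,          # neutral
        "fine": 7.0, "great": 8.0,        # positive
    }
    emotions = {
        "sad": {"sadness"},
        "sick": {"sadness", "disgust"},
        "pandemic": {"fear"},  # ignored: not in valence scores
        "fine": {"joy", "trust"},
        "great": {"joy", "anticipation"},
    }
    emotions = {w: e for w, e in emotions.items() if w in scores}
    return AffectLexicon.from_scores(scores, emotions)


@pytest.fixture(scope="session")
def antonym_table() -> dict[str, tuple[str, ...]]:
    return {"good": ("bad", "awful"), "great": ("sad",), "fine": ("sick",)}


@pytest.fixture(scope="session")
def tiny_dictionary() -> EmotionalDictionary:
    return EmotionalDictionary(
        valence_label={
            "sad": "negative", "sick": "negative",
            "fine": "positive", "great": "positive",
            "normal": "neutral", "calm": "neutral",
        }
    )


@pytest.fixture
def labeled_triangle_graph() -> nx.Graph:
    """Two triangles sharing an edge: (a,b,c) all positive, (b,c,d) mixed."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("b", "d"), ("c", "d")])
    labels = {"a": "positive", "b": "positive", "c": "positive", "d": "negative"}
    nx.set_node_attributes(g, labels, "sentiment_label")
    return g


def random_labeled_graph(rng: np.random.Generator, n_max: int = 12,
                         p: float = 0.4) -> nx.Graph:
    """Random simple labeled graph for oracle-equivalence checks."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    labels = {
        i: ("positive", "negative", "neutral")[int(rng.integers(3))] for i in g.nodes
    }
    nx.set_node_attributes(g, labels, "sentiment_label")
    return g
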