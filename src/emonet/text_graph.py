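"""Note corpora and word-word co-occurrence networks.

Two words are linked when one occurs immediately after the other in at
least one sentence. Everything — pronouns, stopwords, negations — stays in
the network as a node; filtering happens only downstream (last-word
extraction, sampling pools). Prominence is measured by closeness centrality
C_i = (N−1)/Σ_j d_ij, computed within each connected component on the
unweighted topology.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .lexicon import AffectLexicon
from .stopwords import STOPWORDS

logger = logging.getLogger(__name__)

ALL_SENTENCES = "all_sentences"
LAST_SENTENCES = "last_sentences"

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
# Lowercase word tokens; intra-word apostrophes are kept ("can't") and
# underscores allowed so anonymized placeholders ("name_anna") stay whole.
_TOKEN = re.compile(r"[a-z0-9_]+(?:'[a-z0-9_]+)*")

#: Default pattern for anonymized name placeholders in pre-processed corpora.
DEFAULT_NAME_PATTERN = r"^name_\w+$"


def tokenize_sentences(text: str) -> list[list[str]]:
    """Split *text* into sentences at ``. ! ?`` and lowercase word tokens."""
    sentences = []
    for chunk in _SENTENCE_SPLIT.split(text.lower()):
        tokens = _TOKEN.findall(chunk)
        if tokens:
            sentences.append(tokens)
    return sentences


@dataclass(frozen=True)
class Note:
    note_id: str
    sentences: tuple[tuple[str, ...], ...]

    @property
    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]

    @property
    def last_sentence(self) -> tuple[str, ...]:
        return self.sentences[-1]


@dataclass(frozen=True)
class NoteCorpus:
    notes: tuple[Note, ...]
    stopwords: frozenset[str] = STOPWORDS
    name_pattern: str = DEFAULT_NAME_PATTERN
    _name_re: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_name_re", re.compile(self.name_pattern))

    def __len__(self) -> int:
        return len(self.notes)

    def is_stopword(self, token: str) -> bool:
        return token in self.stopwords

    def is_name_placeholder(self, token: str) -> bool:
        return bool(self._name_re.match(token))

    def sentences(self, scope: str = ALL_SENTENCES) -> list[tuple[str, ...]]:
        if scope == ALL_SENTENCES:
            return [s for n in self.notes for s in n.sentences]
        if scope == LAST_SENTENCES:
            return [n.last_sentence for n in self.notes]
        raise ValueError(f"unknown scope {scope!r}")


def corpus_from_texts(
    records: Iterable[tuple[str, str]],
    stopwords: frozenset[str] = STOPWORDS,
    min_sentences: int = 2,
    name_pattern: str = DEFAULT_NAME_PATTERN,
) -> NoteCorpus:
    """Tokenize (note_id, text) records, dropping notes shorter than
    *min_sentences* sentences."""
    notes, dropped = [], 0
    for note_id, text in records:
        sentences = tokenize_sentences(text)
        if len(sentences) < min_sentences:
            dropped += 1
            continue
        notes.append(Note(note_id=str(note_id), sentences=tuple(map(tuple, sentences))))
    logger.info("corpus: %d notes retained, %d dropped (<%d sentences)",
                len(notes), dropped, min_sentences)
    if not notes:
        raise ValueError("empty corpus after filtering")
    return NoteCorpus(notes=tuple(notes), stopwords=stopwords, name_pattern=name_pattern)


def load_corpus(
    path: str | Path,
    stopwords: frozenset[str] = STOPWORDS,
    min_sentences: int = 2,
    name_pattern: str = DEFAULT_NAME_PATTERN,
) -> NoteCorpus:
    """Load a corpus from a directory of ``.txt`` files (one note each) or a
    CSV with columns ``note_id,text``."""
    p = Path(path)
    if p.is_dir():
        records = [(f.stem, f.read_text(encoding="utf-8")) for f in sorted(p.glob("*.txt"))]
    elif p.suffix.lower() == ".csv":
        df = pd.read_csv(p, dtype=str)
        records = list(zip(df["note_id"], df["text"].fillna("")))
    else:
        raise ValueError(f"unsupported corpus input: {p}")
    return corpus_from_texts(records, stopwords=stopwords,
                             min_sentences=min_sentences, name_pattern=name_pattern)


def build_cooccurrence_network(
    corpus: NoteCorpus,
    scope: str = ALL_SENTENCES,
    lexicon: AffectLexicon | None = None,
) -> nx.Graph:
    """Build the sentence-adjacent bigram network for *scope*.

    The graph is simple and undirected: repeated bigrams accumulate in the
    edge ``weight`` attribute, adjacent repetition of a token yields no
    self-loop. When *lexicon* is given every node gets a
    ``sentiment_label`` attribute (out-of-lexicon words are neutral).
    """
    sentences = corpus.sentences(scope)
    if not sentences:
        raise ValueError(f"scope {scope!r} contains no sentences")
    g = nx.Graph(scope=scope)
    for sent in sentences:
        for tok in sent:
            g.add_node(tok)
        for u, v in zip(sent, sent[1:]):
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    if lexicon is not None:
        annotate_sentiment(g, lexicon)
    return g


def annotate_sentiment(g: nx.Graph, lexicon: AffectLexicon) -> None:
    """Attach each node's lexicon sentiment label (neutral if unknown)."""
    nx.set_node_attributes(
        g, {n: lexicon.sentiment(n) for n in g.nodes}, "sentiment_label"
    )


def closeness(g: nx.Graph) -> dict[str, float]:
    """Closeness C_i = (N−1)/Σ_j d_ij within each connected component.

    Distances are unweighted shortest-path lengths; nodes in singleton
    components get C_i = 0. Cross-component distances are never summed.
    """
    return nx.closeness_centrality(g, wf_improved=False)


@dataclass(frozen=True)
class HomophilyResult:
    kendall_tau: float
    p_value: float
    defined: bool = True


_ORDINAL = {"negative": -1, "neutral": 0, "positive": 1}


def edge_valence_homophily(g: nx.Graph) -> HomophilyResult:
    """Kendall tau-b between the sentiment labels of linked words.

    Each undirected edge contributes both orientations so the statistic is
    orientation-invariant; positive tau indicates valence homophily. When
    every node label is identical tau is undefined and the result flagged.
    """
    if g.number_of_edges() < 2:
        raise ValueError("homophily needs at least 2 edges")
    x, y = [], []
    for u, v in g.edges:
        lu = _ORDINAL[g.nodes[u]["sentiment_label"]]
        lv = _ORDINAL[g.nodes[v]["sentiment_label"]]
        x.extend((lu, lv))
        y.extend((lv, lu))
    if len(set(x)) < 2:
        return HomophilyResult(float("nan"), float("nan"), defined=False)
    res = stats.kendalltau(x, y)
    return HomophilyResult(float(res.statistic), float(res.pvalue))


def last_words(corpus: NoteCorpus) -> set[str]:
    """Unique tokens of all final sentences, minus stopwords and name
    placeholders."""
    words: set[str] = set()
    for note in corpus.notes:
        for tok in note.last_sentence:
            if corpus.is_stopword(tok) or corpus.is_name_placeholder(tok):
                continue
            words.add(tok)
    return words


def semantic_frame(
    g: nx.Graph, word: str, lexicon: AffectLexicon | None = None
) -> dict[str, dict]:
    """Network neighborhood of *word* with each neighbor's affect.

    Approximates the semantic frame of a concept: the words it directly
    co-occurs with, each annotated with its sentiment label and emotions.
    """
    if word not in g:
        raise KeyError(f"word {word!r} is not a node of the network")
    frame = {}
    for nb in g.neighbors(word):
        label = g.nodes[nb].get("sentiment_label")
        if label is None and lexicon is not None:
            label = lexicon.sentiment(nb)
        emotions = lexicon.emotions_of(nb) if lexicon is not None else frozenset()
        frame[nb] = {"sentiment_label": label, "emotions": emotions}
    return frame


def export_network(g: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Write edge-list TSV (u, v, weight) and node-table CSV
    (word, sentiment_label, closeness, component_id)."""
    pd.DataFrame(
        [(u, v, d.get("weight", 1)) for u, v, d in g.edges(data=True)],
        columns=["u", "v", "weight"],
    ).to_csv(edges_path, sep="\t", index=False)
    close = closeness(g)
    comp_id = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_id[n] = i
    pd.DataFrame(
        [
            (n, g.nodes[n].get("sentiment_label", ""), close[n], comp_id[n])
            for n in g.nodes
        ],
        columns=["word", "sentiment_label", "closeness", "component_id"],
    ).to_csv(nodes_path, index=False)
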