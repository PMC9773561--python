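"""Ordered emotional word lists and windowed co-occurrence networks.

A text (a note, or one fluency-task response) is reduced to the ordered
list of its dictionary stems: stem every token, keep only stems in the
emotional dictionary, preserve order, keep duplicates. Lists shorter than
an inclusion threshold (default 5 emotional words) are dropped.

Lists are turned into a network by windowed co-occurrence: two stems
co-occur whenever they lie within ``a`` positions of one another inside a
list (windows never cross list boundaries). Pairs seen at least
``min_count`` times become candidate edges and are kept only when their
count beats a one-sided binomial null that accounts for stem frequency —
frequent stems must co-occur more often than rare ones before the link is
believed.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import binom

from .lexicon import EmotionalDictionary
from .stemming import stem as default_stem
from .text_graph import NoteCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmotionalWordList:
    """Ordered dictionary stems from one source text with parallel valence
    labels. Duplicates are kept in order of appearance."""

    source_id: str
    stems: tuple[str, ...]
    valence_seq: tuple[str, ...]

    def __post_init__(self):
        if len(self.stems) != len(self.valence_seq):
            raise ValueError("stems and valence_seq must be parallel")

    def __len__(self) -> int:
        return len(self.stems)


def list_from_tokens(
    source_id: str,
    tokens: Iterable[str],
    dictionary: EmotionalDictionary,
    stemmer: Callable[[str], str] = default_stem,
) -> EmotionalWordList:
    stems = [s for s in (stemmer(t) for t in tokens) if s in dictionary]
    return EmotionalWordList(
        source_id=source_id,
        stems=tuple(stems),
        valence_seq=tuple(dictionary.label(s) for s in stems),
    )


def extract_emotional_lists(
    corpus: NoteCorpus,
    dictionary: EmotionalDictionary,
    min_length: int = 5,
    stemmer: Callable[[str], str] = default_stem,
) -> list[EmotionalWordList]:
    """Transform each note into its ordered emotional word list.

    Punctuation is already gone at tokenization; lists with fewer than
    *min_length* dictionary stems are dropped (and the drop count logged).
    """
    if len(dictionary) == 0:
        raise ValueError("empty emotional dictionary")
    lists, dropped = [], 0
    for note in corpus.notes:
        lst = list_from_tokens(note.note_id, note.tokens, dictionary, stemmer)
        if len(lst) < min_length:
            dropped += 1
            continue
        lists.append(lst)
    logger.info("emotional lists: %d retained, %d dropped (<%d stems)",
                len(lists), dropped, min_length)
    return lists


def windowed_pair_counts(
    lists: Sequence[EmotionalWordList | Sequence[str]], a: int = 2
) -> tuple[Counter, int]:
    """Co-occurrence counts k(u,v) within window *a* and the total number
    of positional pairs T.

    Every unordered positional pair at distance ≤ a counts once; a stem
    never pairs with itself (no self-edges). A list of length ℓ contributes
    Σ_{d=1..a} max(0, ℓ−d) positional pairs to T.
    """
    if a < 1:
        raise ValueError("window size a must be >= 1")
    counts: Counter = Counter()
    total_pairs = 0
    for lst in lists:
        stems = lst.stems if isinstance(lst, EmotionalWordList) else tuple(lst)
        n = len(stems)
        for d in range(1, a + 1):
            total_pairs += max(0, n - d)
        for i in range(n):
            for j in range(i + 1, min(i + a + 1, n)):
                if stems[i] == stems[j]:
                    continue
                key = (stems[i], stems[j]) if stems[i] < stems[j] else (stems[j], stems[i])
                counts[key] += 1
    return counts, total_pairs


def build_recall_network(
    lists: Sequence[EmotionalWordList],
    a: int = 2,
    min_count: int = 2,
    alpha: float = 0.05,
    pair_rate: str = "product",
    dictionary: EmotionalDictionary | None = None,
) -> nx.Graph:
    """Windowed co-occurrence network with binomial link filtering.

    A candidate pair with count k is retained iff k ≥ *min_count* and the
    one-sided tail P(X ≥ k) < *alpha* for X ~ Binomial(T, p_uv), where T is
    the total number of within-window positional pairs and p_uv the
    expected pair rate under independent placement given the empirical stem
    frequencies f: ``f_u · f_v`` (*pair_rate*="product") or ``2·f_u·f_v``
    ("unordered"). Nodes are the stems incident to retained edges, labeled
    with their valence; edges carry ``k`` and ``p_value``. The full
    candidate table (including rejected pairs) is stored in
    ``g.graph["candidates"]``.
    """
    if a < 1 or min_count < 1:
        raise ValueError("window size and min_count must be >= 1")
    if pair_rate not in ("product", "unordered"):
        raise ValueError(f"unknown pair_rate {pair_rate!r}")
    usable = [l for l in lists if len(l) >= 2]
    if not usable:
        raise ValueError("need at least one list of length >= 2")
    counts, total_pairs = windowed_pair_counts(usable, a=a)
    freq: Counter = Counter()
    for lst in usable:
        freq.update(lst.stems)
    n_tokens = sum(freq.values())

    label_of: dict[str, str] = {}
    for lst in usable:
        for s, lab in zip(lst.stems, lst.valence_seq):
            label_of.setdefault(s, lab)
    if dictionary is not None:
        for s in label_of:
            label_of[s] = dictionary.label(s)

    rows = []
    g = nx.Graph(a=a, min_count=min_count, alpha=alpha, total_pairs=total_pairs)
    factor = 2.0 if pair_rate == "unordered" else 1.0
    for (u, v), k in sorted(counts.items()):
        p_uv = factor * (freq[u] / n_tokens) * (freq[v] / n_tokens)
        p_value = float(binom.sf(k - 1, total_pairs, min(p_uv, 1.0)))
        retained = k >= min_count and p_value < alpha
        rows.append((u, v, k, p_value, retained))
        if retained:
            g.add_node(u, sentiment_label=label_of[u])
            g.add_node(v, sentiment_label=label_of[v])
            g.add_edge(u, v, k=k, p_value=p_value)
    g.graph["candidates"] = pd.DataFrame(
        rows, columns=["u", "v", "k", "p_value", "retained"]
    )
    logger.info("recall network: %d nodes, %d links (of %d candidate pairs)",
                g.number_of_nodes(), g.number_of_edges(), len(rows))
    return g


def export_recall_network(g: nx.Graph, path) -> None:
    """Write the candidate edge table as TSV (u, v, k, p_value, retained)."""
    g.graph["candidates"].to_csv(path, sep="\t", index=False)


def lists_to_frame(lists: Sequence[EmotionalWordList]) -> pd.DataFrame:
    """Long-format table (source_id, position, stem, valence)."""
    rows = [
        (lst.source_id, i, s, v)
        for lst in lists
        for i, (s, v) in enumerate(zip(lst.stems, lst.valence_seq))
    ]
    return pd.DataFrame(rows, columns=["source_id", "position", "stem", "valence"])


def lists_from_frame(df: pd.DataFrame) -> list[EmotionalWordList]:
    lists = []
    for sid, grp in df.groupby("source_id", sort=False):
        grp = grp.sort_values("position")
        lists.append(
            EmotionalWordList(
                source_id=str(sid),
                stems=tuple(grp["stem"]),
                valence_seq=tuple(grp["valence"]),
            )
        )
    return lists
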