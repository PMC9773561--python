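"""Emotional entropy, triad taxonomy, and the emotional-complexity degree.

Emotional entropy h is the two-event Shannon entropy (base 2) of the
same/different indicator string built from transitions between adjacent
valence labels in an ordered word list: alternating lists that bunch all
their switches score low, lists whose switches are scattered score high,
and 0 ≤ h ≤ 1 always.

Emotional complexity is the affective analog of structural balance, with
the sign carried by nodes instead of edges: a closed triangle of words is
*incoherent* when its three valence labels include at least one positive
and one negative word (neutral creates no contrast), and the complexity
degree c of a labeled network is the fraction of incoherent triangles,
c = n_i / (n_c + n_i).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .lexicon import NEGATIVE, NEUTRAL, POSITIVE, SENTIMENT_LABELS

#: Compact signature characters, in canonical order.
_SIGN = {POSITIVE: "+", NEGATIVE: "-", NEUTRAL: "n"}
_SIGN_ORDER = {"+": 0, "-": 1, "n": 2}

#: Integer codes used by the vectorized census (and the null models).
LABEL_CODES: dict[str, int] = {POSITIVE: 0, NEGATIVE: 1, NEUTRAL: 2}

#: The 10 unordered triad signatures, canonical order.
SIGNATURES = (
    "+++", "++-", "++n", "+--", "+-n", "+nn", "---", "--n", "-nn", "nnn",
)


@dataclass(frozen=True)
class TransitionRecord:
    indicator: tuple[int, ...]
    p_same: float
    p_diff: float
    h: float


def emotional_entropy(valence_seq: Sequence[str]) -> TransitionRecord:
    """Entropy of same/different valence transitions in an ordered list.

    Starting from the first position, each adjacent pair contributes 0 when
    the labels match and 1 otherwise; h is the Shannon entropy (bits) of
    the two events, with the 0·log 0 := 0 convention.
    """
    if len(valence_seq) < 2:
        raise ValueError("no transitions: sequence must have length >= 2")
    for lab in valence_seq:
        if lab not in SENTIMENT_LABELS:
            raise ValueError(f"invalid valence label {lab!r}")
    indicator = tuple(
        0 if a == b else 1 for a, b in zip(valence_seq, valence_seq[1:])
    )
    n = len(indicator)
    p_diff = sum(indicator) / n
    p_same = 1.0 - p_diff
    h = 0.0
    for p in (p_same, p_diff):
        if p > 0.0:
            h -= p * np.log2(p)
    return TransitionRecord(indicator=indicator, p_same=p_same, p_diff=p_diff, h=float(h))


def classify_triad(labels: Sequence[str]) -> str:
    """Classify a triangle's three node labels as coherent or incoherent.

    Incoherent iff both a positive and a negative label are present;
    neutral words raise no contrast with either polarity.
    """
    if len(labels) != 3:
        raise ValueError("a triad has exactly 3 labels")
    s = set()
    for lab in labels:
        if lab not in SENTIMENT_LABELS:
            raise ValueError(f"invalid valence label {lab!r}")
        s.add(lab)
    return "incoherent" if POSITIVE in s and NEGATIVE in s else "coherent"


def triad_signature(labels: Sequence[str]) -> str:
    """Canonical unordered signature string, e.g. ``'++n'``."""
    signs = sorted((_SIGN[lab] for lab in labels), key=_SIGN_ORDER.__getitem__)
    return "".join(signs)


@dataclass(frozen=True)
class TriadCensus:
    counts: Mapping[str, int]
    n_coherent: int
    n_incoherent: int
    c: float | None  # None when the graph has no triangles

    @property
    def n_triangles(self) -> int:
        return self.n_coherent + self.n_incoherent


_INCOHERENT_SIGS = frozenset(s for s in SIGNATURES if "+" in s and "-" in s)


def triangle_list(g: nx.Graph) -> list[tuple]:
    """All closed triangles of a simple graph, each unordered triple once."""
    order = {n: i for i, n in enumerate(g.nodes)}
    triangles = []
    for u in g.nodes:
        nbrs_u = {w for w in g.neighbors(u) if order[w] > order[u]}
        for v in nbrs_u:
            for w in nbrs_u:
                if order[w] > order[v] and g.has_edge(v, w):
                    triangles.append((u, v, w))
    return triangles


def census_from_codes(tri_codes: np.ndarray) -> tuple[Counter, int]:
    """Signature counts and incoherent total from a (T, 3) label-code array.

    Vectorized core shared with the network null models, where the triangle
    list is fixed and only labels change across iterations.
    """
    counts: Counter = Counter()
    if tri_codes.size == 0:
        return counts, 0
    npos = (tri_codes == LABEL_CODES[POSITIVE]).sum(axis=1)
    nneg = (tri_codes == LABEL_CODES[NEGATIVE]).sum(axis=1)
    sig_of = {}
    for sig in SIGNATURES:
        sig_of[(sig.count("+"), sig.count("-"))] = sig
    key = npos * 4 + nneg
    for k in np.unique(key):
        cnt = int((key == k).sum())
        counts[sig_of[(int(k) // 4, int(k) % 4)]] = cnt
    n_inc = int(((npos > 0) & (nneg > 0)).sum())
    return counts, n_inc


def triad_census(
    g: nx.Graph, labels: Mapping[str, str] | None = None
) -> TriadCensus:
    """Enumerate all triangles and tally valence signatures.

    Labels come from the ``sentiment_label`` node attribute unless an
    explicit mapping is given; an unlabeled node in a triangle is an error.
    With no triangles c is undefined (``None``).
    """
    tris = triangle_list(g)
    get = (labels or {}).get if labels is not None else lambda n, d=None: g.nodes[n].get(
        "sentiment_label", d
    )
    code_rows = []
    for tri in tris:
        row = []
        for node in tri:
            lab = get(node, None)
            if lab is None:
                raise ValueError(f"node {node!r} in a triangle has no valence label")
            if lab not in LABEL_CODES:
                raise ValueError(f"invalid valence label {lab!r} on node {node!r}")
            row.append(LABEL_CODES[lab])
        code_rows.append(row)
    tri_codes = np.asarray(code_rows, dtype=np.int8).reshape(len(tris), 3)
    counts, n_inc = census_from_codes(tri_codes)
    total = len(tris)
    c = None if total == 0 else n_inc / total
    full = {sig: counts.get(sig, 0) for sig in SIGNATURES}
    return TriadCensus(counts=full, n_coherent=total - n_inc, n_incoherent=n_inc, c=c)


def ordered_triad_counts(valence_seq: Sequence[str]) -> Counter:
    """Counts of consecutive ordered label triples in a word list.

    Sliding windows of 3 adjacent labels, e.g. key ('+','-','+') counts the
    fixed-order positive–negative–positive patterns of a narrative.
    Sequences shorter than 3 give empty counts.
    """
    for lab in valence_seq:
        if lab not in SENTIMENT_LABELS:
            raise ValueError(f"invalid valence label {lab!r}")
    signs = [_SIGN[lab] for lab in valence_seq]
    return Counter(
        tuple(signs[i : i + 3]) for i in range(len(signs) - 2)
    )
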