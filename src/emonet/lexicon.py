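"""Affective lexicons: valence scores, quartile sentiment labels, emotions,
and negation resolution.

Every word in an :class:`AffectLexicon` carries a continuous valence score,
a discrete 3-way sentiment label derived from the lexicon-wide quartiles of
those scores (negative ≤ Q1, positive ≥ Q3, neutral in between), an optional
subset of the eight basic emotions (joy, trust, fear, surprise, sadness,
disgust, anger, anticipation), and a stem. The :class:`EmotionalDictionary`
is the separate inventory of emotional stems (fluency-task derived) used to
extract ordered emotional word lists from running text.

Negated phrases ("not good") are resolved to an antonym ("bad") so that the
flipped affect, not the literal token, enters sentiment and emotion counts.
"""

from __future__ import annotations

import csv
import logging
import math
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stemming import stem as default_stem

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
SENTIMENT_LABELS = (POSITIVE, NEGATIVE, NEUTRAL)

EMOTIONS = (
    "joy",
    "trust",
    "fear",
    "surprise",
    "sadness",
    "disgust",
    "anger",
    "anticipation",
)

#: Negation markers whose scope is the single following content token.
NEGATION_MARKERS = frozenset({"not", "no", "never", "n't", "cannot", "without"})

_INVERTED = {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE, NEUTRAL: NEUTRAL}


def assign_sentiment_labels(valence_scores: Mapping[str, float]) -> dict[str, str]:
    """Discretize valence scores into positive/negative/neutral by quartiles.

    Words at or below the first quartile of the score distribution are
    negative, at or above the third quartile positive, in between neutral.
    Quartiles use inclusive linear interpolation. When Q1 == Q3 (a
    degenerate, concentrated distribution) the boundary comparisons become
    strict so that words at the common quartile value are neutral; an
    all-equal lexicon is therefore entirely neutral.
    """
    if not valence_scores:
        raise ValueError("empty lexicon")
    for word, score in valence_scores.items():
        if not math.isfinite(score):
            raise ValueError(f"non-finite valence score for word {word!r}")
    values = np.fromiter(valence_scores.values(), dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    labels: dict[str, str] = {}
    degenerate = q1 == q3
    for word, score in valence_scores.items():
        if (score < q1) if degenerate else (score <= q1):
            labels[word] = NEGATIVE
        elif (score > q3) if degenerate else (score >= q3):
            labels[word] = POSITIVE
        else:
            labels[word] = NEUTRAL
    return labels


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    valence: float
    sentiment_label: str
    emotions: frozenset[str]
    stem: str


class AffectLexicon:
    """Word → (valence, sentiment label, emotion set, stem) lookup.

    Lookups are case-insensitive; unknown words have an empty emotion set
    and a configurable default sentiment (neutral).
    """

    def __init__(self, entries: Mapping[str, LexiconEntry]):
        self._entries = {w.lower(): e for w, e in entries.items()}

    @classmethod
    def from_scores(
        cls,
        valence_scores: Mapping[str, float],
        emotions: Mapping[str, Iterable[str]] | None = None,
        stemmer: Callable[[str], str] = default_stem,
    ) -> "AffectLexicon":
        """Build a lexicon from raw valence scores and an emotion map."""
        labels = assign_sentiment_labels(valence_scores)
        emotions = emotions or {}
        emo_lower = {w.lower(): frozenset(e) for w, e in emotions.items()}
        bad = set().union(*emo_lower.values()) - set(EMOTIONS) if emo_lower else set()
        if bad:
            raise ValueError(f"unknown emotions: {sorted(bad)}")
        entries = {}
        for word, score in valence_scores.items():
            w = word.lower()
            entries[w] = LexiconEntry(
                word=w,
                valence=float(score),
                sentiment_label=labels[word],
                emotions=emo_lower.get(w, frozenset()),
                stem=stemmer(w),
            )
        return cls(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __iter__(self):
        return iter(self._entries)

    def entry(self, word: str) -> LexiconEntry | None:
        return self._entries.get(word.lower())

    def valence(self, word: str) -> float | None:
        e = self.entry(word)
        return None if e is None else e.valence

    def sentiment(self, word: str, default: str = NEUTRAL) -> str:
        """Sentiment label of *word*; *default* for out-of-lexicon words."""
        e = self.entry(word)
        return default if e is None else e.sentiment_label

    def emotions_of(self, word: str) -> frozenset[str]:
        """Emotion subset elicited by *word* (empty for unknown words)."""
        e = self.entry(word)
        return frozenset() if e is None else e.emotions

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in SENTIMENT_LABELS}
        for e in self._entries.values():
            counts[e.sentiment_label] += 1
        return counts

    def words(self) -> list[str]:
        return list(self._entries)


@dataclass(frozen=True)
class EmotionalDictionary:
    """Set of emotional stems with a valence label per stem."""

    valence_label: Mapping[str, str]
    stems: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        stems = frozenset(self.valence_label)
        object.__setattr__(self, "stems", stems)
        for s in stems:
            if s != s.lower():
                raise ValueError(f"dictionary stem not lowercase: {s!r}")
        bad = set(self.valence_label.values()) - set(SENTIMENT_LABELS)
        if bad:
            raise ValueError(f"invalid valence labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stems)

    def __contains__(self, stem: str) -> bool:
        return stem in self.stems

    def label(self, stem: str) -> str:
        return self.valence_label[stem]


@dataclass(frozen=True)
class ResolvedToken:
    """Effective affect carrier for one surface token.

    ``word`` is the token whose affect enters the counts (the antonym when a
    negation was resolved); ``inverted`` marks the no-antonym fallback where
    the original token is kept with its sentiment label flipped.
    """

    word: str
    sentiment_label: str
    emotions: frozenset[str]
    negated: bool = False
    inverted: bool = False


def resolve_negation(
    negator: str,
    word: str,
    lexicon: AffectLexicon,
    antonyms: Mapping[str, Sequence[str]] | None,
) -> ResolvedToken:
    """Resolve a (negation marker, word) pair to its affect carrier.

    The antonym chosen is the lexicographically first one present in the
    valence lexicon. Without any usable antonym the original word is kept
    and its sentiment label inverted (positive↔negative, neutral unchanged).
    """
    if negator.lower() not in NEGATION_MARKERS:
        raise ValueError(f"{negator!r} is not a configured negation marker")
    w = word.lower()
    candidates = sorted(a.lower() for a in (antonyms or {}).get(w, ()))
    for cand in candidates:
        if cand in lexicon:
            return ResolvedToken(
                word=cand,
                sentiment_label=lexicon.sentiment(cand),
                emotions=lexicon.emotions_of(cand),
                negated=True,
            )
    logger.debug("no antonym for negated word %r; inverting its label", w)
    return ResolvedToken(
        word=w,
        sentiment_label=_INVERTED[lexicon.sentiment(w)],
        emotions=lexicon.emotions_of(w),
        negated=True,
        inverted=True,
    )


def effective_affect_tokens(
    tokens: Sequence[str],
    lexicon: AffectLexicon,
    antonyms: Mapping[str, Sequence[str]] | None = None,
) -> list[ResolvedToken]:
    """Map a token sequence to the affect carriers used for counting.

    Each token contributes one carrier. A token immediately following a
    negation marker is replaced by its resolved antonym (or kept with an
    inverted label); the marker itself still contributes as a plain token.
    """
    out: list[ResolvedToken] = []
    prev_negator: str | None = None
    for tok in tokens:
        t = tok.lower()
        if prev_negator is not None:
            out.append(resolve_negation(prev_negator, t, lexicon, antonyms))
            prev_negator = None
        else:
            out.append(
                ResolvedToken(
                    word=t,
                    sentiment_label=lexicon.sentiment(t),
                    emotions=lexicon.emotions_of(t),
                )
            )
        prev_negator = t if t in NEGATION_MARKERS else None
    return out


# ---------------------------------------------------------------------------
# File dialects: two-column TSV for valence, three-column TSV for emotions,
# one stem per line (optional label column) for the emotional dictionary,
# two-column TSV for antonyms.


def load_valence_tsv(path: str | Path) -> dict[str, float]:
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            scores[row[0].lower()] = float(row[1])
    return scores


def load_emotion_tsv(path: str | Path) -> dict[str, set[str]]:
    emo: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            word, emotion, flag = row[0].lower(), row[1].lower(), row[2]
            if int(flag):
                emo.setdefault(word, set()).add(emotion)
    return emo


def load_dictionary(
    path: str | Path, lexicon: AffectLexicon | None = None
) -> EmotionalDictionary:
    """Load an emotional dictionary: ``stem[\\tlabel]`` per line.

    When the label column is absent the valence label is taken from
    *lexicon* (matched by stem, falling back to neutral).
    """
    by_stem: dict[str, str] = {}
    if lexicon is not None:
        for w in lexicon.words():
            e = lexicon.entry(w)
            by_stem.setdefault(e.stem, e.sentiment_label)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            row = line.strip().split("\t")
            if not row or not row[0] or row[0].startswith("#"):
                continue
            stem_ = row[0].lower()
            labels[stem_] = row[1] if len(row) > 1 else by_stem.get(stem_, NEUTRAL)
    return EmotionalDictionary(valence_label=labels)


def load_antonyms_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    table: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table.setdefault(row[0].lower(), []).append(row[1].lower())
    return {w: tuple(a) for w, a in table.items()}
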