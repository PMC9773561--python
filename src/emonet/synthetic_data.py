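"""Synthetic lexicons, note corpora, and fluency-style recall lists.

The generator stands in for sensitive real data (suicide-note corpora,
emotional-recall responses) so that every pipeline stage runs end-to-end
without any download. It emulates the statistical shape the analysis
assumes:

* a valence lexicon of pseudo-words whose quartile labeling recovers the
  requested class sizes exactly, plus an emotional dictionary of stems;
* note corpora of ~139 notes averaging ~120 tokens whose final sentences
  run 16 ± 2 tokens, with stopwords interleaved and occasional negations;
* recall lists of exactly 10 emotional stems per respondent, each tagged
  with a screening score (score 0 marks the "healthy" comparison group);
* valence dynamics from a first-order Markov chain over the three valence
  classes, P = ρ·I + (1−ρ)·π, whose stationary distribution is the target
  mix π and whose stay-boost ρ produces weak valence homophily;
* Zipf-distributed word choice within each valence class, so frequent
  stems repeat across texts the way real emotional vocabulary does.

Content words are pseudo-words (random CV-syllable strings), so no real
lexicon is shipped; runs on real lexicon files are a drop-in replacement.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .lexicon import (
    EMOTIONS,
    NEGATIVE,
    NEUTRAL,
    POSITIVE,
    AffectLexicon,
    EmotionalDictionary,
)
from .stemming import stem as stem_word
from .text_graph import Note, NoteCorpus
from .recall_graph import EmotionalWordList

_CLASSES = (POSITIVE, NEGATIVE, NEUTRAL)

# Emotion-assignment probabilities per valence class: positive words skew
# joy/trust/anticipation, negative words fear/sadness/anger/disgust.
DEFAULT_EMOTION_PROBS: dict[str, dict[str, float]] = {
    POSITIVE: {"joy": 0.5, "trust": 0.4, "anticipation": 0.3, "surprise": 0.15,
               "fear": 0.02, "sadness": 0.02, "disgust": 0.02, "anger": 0.02},
    NEGATIVE: {"sadness": 0.5, "fear": 0.4, "anger": 0.3, "disgust": 0.25,
               "surprise": 0.15, "joy": 0.02, "trust": 0.02, "anticipation": 0.02},
    NEUTRAL: {emo: 0.05 for emo in EMOTIONS},
}

_SMALL_STOPWORDS = (
    "the", "and", "i", "to", "my", "of", "a", "you", "for", "me", "is", "it",
    "this", "that", "so", "all", "be", "was", "have", "in",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """All the knobs of the synthetic world, with study-shaped defaults."""

    # corpus shape
    n_notes: int = 139
    note_length_mean: float = 120.0
    note_length_sd: float = 30.0
    sentence_length_mean: float = 12.0
    sentence_length_sd: float = 4.0
    last_sentence_length_mean: float = 16.0
    last_sentence_length_sd: float = 2.0
    # valence dynamics: stationary mix (pos, neg, neu) + stay boost
    valence_mix: tuple[float, float, float] = (0.52, 0.31, 0.17)
    stay_boost: float = 0.15
    # recall task
    n_lists: int = 200
    list_length: int = 10
    p_screen_zero: float = 0.5
    screen_poisson_mean: float = 3.0
    # lexicon
    n_positive: int = 1250
    n_neutral: int = 2500
    n_negative: int = 1250
    dictionary_size: int = 475
    emotion_probs: dict = field(default_factory=lambda: DEFAULT_EMOTION_PROBS)
    # text texture
    zipf_exponent: float = 1.3
    dictionary_rate: float = 0.3
    stopword_rate: float = 0.35
    negation_rate: float = 0.02
    inflection_rate: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if abs(sum(self.valence_mix) - 1.0) > 1e-9:
            raise ValueError("valence_mix must sum to 1")
        if min(self.valence_mix) < 0:
            raise ValueError("valence_mix entries must be non-negative")
        if not 0 <= self.stay_boost <= 1:
            raise ValueError("stay_boost must be in [0, 1]")
        for name in ("n_notes", "n_lists", "list_length",
                     "n_positive", "n_neutral", "n_negative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 3×3 matrix P = ρ·I + (1−ρ)·π over (pos, neg, neu)."""
        pi = np.asarray(self.valence_mix)
        p = self.stay_boost * np.eye(3) + (1 - self.stay_boost) * np.tile(pi, (3, 1))
        if np.any(~np.isfinite(p)) or np.any(p.sum(axis=1) == 0):
            raise ValueError("degenerate transition matrix")
        return p / p.sum(axis=1, keepdims=True)

    @classmethod
    def suicide_notes(cls, **overrides) -> "GeneratorSpec":
        """Note-like population: valence mix 52/31/17 (pos/neg/neu)."""
        return cls(**{"valence_mix": (0.52, 0.31, 0.17), **overrides})

    @classmethod
    def healthy_recalls(cls, **overrides) -> "GeneratorSpec":
        """Recall-like population: valence mix 48/22/30 (pos/neg/neu)."""
        return cls(**{"valence_mix": (0.48, 0.22, 0.30), **overrides})

    def with_(self, **overrides) -> "GeneratorSpec":
        return replace(self, **overrides)


_CONSONANTS = "bcfhjklmnprtvwz"  # excludes letters that end like suffixes
_VOWELS = "aeiou"
_SUFFIX_LIKE = ("ness", "ing", "ed", "es", "ly", "s")


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Unique CV-syllable pseudo-words that are fixed points of the stemmer."""
    words: list[str] = []
    while len(words) < n:
        k = rng.integers(2, 4)
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(k)
        ) + _CONSONANTS[rng.integers(len(_CONSONANTS))]
        if w in taken or stem_word(w) != w or w.endswith(_SUFFIX_LIKE):
            continue
        taken.add(w)
        words.append(w)
    return words


def _class_scores(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Valence scores per class such that quartile labeling recovers the
    class sizes exactly (boundary scores are tied when needed)."""
    n = spec.n_positive + spec.n_neutral + spec.n_negative
    q1 = 0.25 * (n - 1)
    q3 = 0.75 * (n - 1)
    n_neg, n_pos = spec.n_negative, spec.n_positive
    if n_neg - 1 < int(np.floor(q1)):
        raise ValueError("negative class too small for quartile labeling")
    if (n - n_pos) > int(np.ceil(q3)):
        raise ValueError("positive class too small for quartile labeling")
    neg = np.linspace(1.0, 3.0, n_neg)
    neg[int(np.floor(q1)):] = 3.0  # tie the boundary so Q1 = 3.0
    neu = np.linspace(4.0, 6.0, spec.n_neutral)
    pos = np.linspace(7.0, 9.0, n_pos)
    first_pos_rank = n - n_pos
    pos[: int(np.ceil(q3)) - first_pos_rank + 1] = 7.0  # tie so Q3 ≤ 7.0
    return neg, neu, pos


def gen_lexicon(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[AffectLexicon, EmotionalDictionary]:
    """Generate the valence/emotion lexicon and the emotional dictionary.

    Scores are constructed so that :func:`assign_sentiment_labels` recovers
    the requested (positive, neutral, negative) class sizes exactly;
    emotions are assigned by independent per-class coin flips; the
    dictionary is a uniform sample of ``dictionary_size`` stems.
    """
    for name in ("n_positive", "n_negative"):
        if getattr(spec, name) < 2:
            raise ValueError("each valence class needs at least 2 words")
    rng = rng or np.random.default_rng(spec.seed)
    neg_s, neu_s, pos_s = _class_scores(spec)
    taken: set[str] = set(_SMALL_STOPWORDS)
    scores: dict[str, float] = {}
    emotions: dict[str, set[str]] = {}
    class_words: dict[str, list[str]] = {}
    for label, class_scores in ((NEGATIVE, neg_s), (NEUTRAL, neu_s), (POSITIVE, pos_s)):
        words = _pseudo_words(rng, len(class_scores), taken)
        class_words[label] = words
        probs = spec.emotion_probs[label]
        for w, s in zip(words, class_scores):
            scores[w] = float(s)
            emos = {emo for emo in EMOTIONS if rng.random() < probs.get(emo, 0.0)}
            if emos:
                emotions[w] = emos
    lexicon = AffectLexicon.from_scores(scores, emotions)

    counts = lexicon.label_counts()
    want = {POSITIVE: spec.n_positive, NEGATIVE: spec.n_negative,
            NEUTRAL: spec.n_neutral}
    if counts != want:
        raise RuntimeError(f"quartile labeling mismatch: {counts} != {want}")

    n_dict = min(spec.dictionary_size, len(scores))
    all_words = sorted(scores)
    picks = rng.choice(len(all_words), size=n_dict, replace=False)
    dict_labels = {all_words[i]: lexicon.sentiment(all_words[i]) for i in picks}
    dictionary = EmotionalDictionary(valence_label=dict_labels)
    return lexicon, dictionary


def _markov_classes(
    n: int, spec: GeneratorSpec, rng: np.random.Generator, state: int | None = None
) -> tuple[np.ndarray, int]:
    """Sample n valence-class codes (0=pos, 1=neg, 2=neu) from the chain."""
    cum_rows = np.cumsum(spec.transition_matrix, axis=1)
    cum_pi = np.cumsum(spec.valence_mix)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        cum = cum_pi if state is None else cum_rows[state]
        state = int(np.searchsorted(cum, rng.random(), side="right"))
        state = min(state, 2)
        out[i] = state
    return out, state


class _WordSampler:
    """Zipf-weighted word choice within each valence class."""

    def __init__(self, spec: GeneratorSpec, lexicon: AffectLexicon,
                 dictionary: EmotionalDictionary, rng: np.random.Generator):
        self._rng = rng
        self._pools: dict[tuple[str, bool], tuple[list[str], np.ndarray]] = {}
        in_dict: dict[str, list[str]] = {c: [] for c in _CLASSES}
        out_dict: dict[str, list[str]] = {c: [] for c in _CLASSES}
        for w in sorted(lexicon.words()):
            e = lexicon.entry(w)
            (in_dict if e.stem in dictionary else out_dict)[e.sentiment_label].append(w)
        for cls in _CLASSES:
            for flag, words in ((True, in_dict[cls]), (False, out_dict[cls])):
                if not words:
                    continue
                words = list(words)
                rng.shuffle(words)
                ranks = np.arange(1, len(words) + 1, dtype=float)
                weights = ranks ** -spec.zipf_exponent
                self._pools[(cls, flag)] = (words, np.cumsum(weights / weights.sum()))

    def draw(self, valence_class: str, from_dictionary: bool) -> str:
        pool = self._pools.get((valence_class, from_dictionary))
        if pool is None:  # fall back to the other stratum of the class
            pool = self._pools[(valence_class, not from_dictionary)]
        words, cum = pool
        i = int(np.searchsorted(cum, self._rng.random(), side="right"))
        return words[min(i, len(words) - 1)]


_CLASS_OF_CODE = {0: POSITIVE, 1: NEGATIVE, 2: NEUTRAL}
_INFLECTIONS = ("s", "ed", "ing", "ness")


def gen_corpus(
    spec: GeneratorSpec,
    lexicon: AffectLexicon,
    dictionary: EmotionalDictionary,
    rng: np.random.Generator | None = None,
) -> NoteCorpus:
    """Generate a note corpus as tokenized sentences.

    Content tokens follow the valence Markov chain (word drawn Zipf-wise
    within the class, from the emotional dictionary with probability
    ``dictionary_rate``); stopwords are interleaved at ``stopword_rate``;
    negation markers precede a content word at ``negation_rate``; inflected
    forms (base + s/ed/ing/ness) appear at ``inflection_rate`` so stemming
    has real work to do. The final sentence runs Normal(16, 2) tokens
    truncated at ≥ 3; every note has at least two sentences.
    """
    rng = rng or np.random.default_rng(spec.seed)
    sampler = _WordSampler(spec, lexicon, dictionary, rng)
    notes = []
    for i in range(spec.n_notes):
        total = max(int(round(rng.normal(spec.note_length_mean, spec.note_length_sd))), 20)
        last_len = max(int(round(rng.normal(spec.last_sentence_length_mean,
                                            spec.last_sentence_length_sd))), 3)
        body = max(total - last_len, 3)
        lengths = []
        while body > 0:
            ln = max(int(round(rng.normal(spec.sentence_length_mean,
                                          spec.sentence_length_sd))), 3)
            lengths.append(min(ln, body))
            body -= lengths[-1]
        lengths.append(last_len)
        state: int | None = None
        sentences = []
        for ln in lengths:
            tokens: list[str] = []
            while len(tokens) < ln:
                if rng.random() < spec.stopword_rate:
                    tokens.append(_SMALL_STOPWORDS[rng.integers(len(_SMALL_STOPWORDS))])
                    continue
                if rng.random() < spec.negation_rate and len(tokens) + 1 < ln:
                    tokens.append("not")
                codes, state = _markov_classes(1, spec, rng, state)
                word = sampler.draw(_CLASS_OF_CODE[int(codes[0])],
                                    rng.random() < spec.dictionary_rate)
                if rng.random() < spec.inflection_rate:
                    word = word + _INFLECTIONS[rng.integers(len(_INFLECTIONS))]
                tokens.append(word)
            sentences.append(tuple(tokens[:ln]))
        notes.append(Note(note_id=f"note{i:04d}", sentences=tuple(sentences)))
    return NoteCorpus(notes=tuple(notes))


@dataclass(frozen=True)
class RecallResponse:
    """One fluency-task response: an emotional word list plus the
    respondent's screening score (0 = no distress symptoms)."""

    word_list: EmotionalWordList
    screening_score: int


def gen_recall_lists(
    spec: GeneratorSpec,
    dictionary: EmotionalDictionary,
    rng: np.random.Generator | None = None,
) -> list[RecallResponse]:
    """Generate recall responses of exactly ``list_length`` distinct stems.

    Stems are drawn by the same Markov mechanism over valence classes
    (Zipf-weighted within class), without replacement within a list.
    Screening scores are 0 with probability ``p_screen_zero`` and
    1 + Poisson(mean) otherwise.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    if spec.list_length > len(dictionary):
        raise ValueError("list_length exceeds dictionary size "
                         "(sampling is without replacement)")
    rng = rng or np.random.default_rng(spec.seed)
    by_class: dict[str, list[str]] = {c: [] for c in _CLASSES}
    for s in sorted(dictionary.stems):
        by_class[dictionary.label(s)].append(s)
    weights = {}
    for cls, stems in by_class.items():
        stems = list(stems)
        rng.shuffle(stems)
        if stems:
            w = np.arange(1, len(stems) + 1, dtype=float) ** -spec.zipf_exponent
            weights[cls] = (stems, np.cumsum(w / w.sum()))
    responses = []
    for i in range(spec.n_lists):
        chosen: list[str] = []
        state: int | None = None
        guard = 0
        while len(chosen) < spec.list_length:
            codes, state = _markov_classes(1, spec, rng, state)
            cls = _CLASS_OF_CODE[int(codes[0])]
            if cls not in weights:
                cls = next(iter(weights))
            stems, cum = weights[cls]
            stem_ = stems[min(int(np.searchsorted(cum, rng.random(), side="right")),
                              len(stems) - 1)]
            guard += 1
            if stem_ in chosen:
                if guard > 200 * spec.list_length:
                    remaining = [s for s in sorted(dictionary.stems) if s not in chosen]
                    stem_ = remaining[rng.integers(len(remaining))]
                else:
                    continue
            chosen.append(stem_)
        lst = EmotionalWordList(
            source_id=f"resp{i:04d}",
            stems=tuple(chosen),
            valence_seq=tuple(dictionary.label(s) for s in chosen),
        )
        score = 0 if rng.random() < spec.p_screen_zero else int(
            1 + rng.poisson(spec.screen_poisson_mean)
        )
        responses.append(RecallResponse(word_list=lst, screening_score=score))
    return responses


def filter_healthy(responses: Sequence[RecallResponse]) -> list[EmotionalWordList]:
    """Word lists of respondents with screening score 0."""
    return [r.word_list for r in responses if r.screening_score == 0]


def corpus_to_texts(corpus: NoteCorpus) -> list[tuple[str, str]]:
    """Render a tokenized corpus back to (note_id, text) records."""
    return [
        (n.note_id, " ".join(" ".join(s) + "." for s in n.sentences))
        for n in corpus.notes
    ]
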