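"""Emotional richness profiles, resampled z-score baselines, and the group
statistics used to compare word populations.

The emotional richness of a text is r_i = m_i / N: the fraction of its N
words eliciting emotion i (a word may elicit several emotions; words
absent from the emotion lexicon still count toward N but elicit nothing).
A profile is judged against a baseline of random same-size samples drawn
without replacement from a pool of comparison words; the per-emotion
z-scores of the observed richness against that resampled distribution are
the data behind "emotional flower" displays, with |z| > 1.96 flagging
significance at the 0.05 level.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lexicon import EMOTIONS, AffectLexicon, effective_affect_tokens

Z_THRESHOLD = 1.96


@dataclass(frozen=True)
class EmotionProfile:
    r: Mapping[str, float]
    m: Mapping[str, int]
    n: int


def emotional_richness(
    words: Sequence[str],
    lexicon: AffectLexicon,
    antonyms: Mapping[str, Sequence[str]] | None = None,
) -> EmotionProfile:
    """Richness profile r_i = m_i / N of a word sequence.

    Negated tokens contribute through their resolved antonym. Every token
    counts toward N regardless of lexicon membership.
    """
    if len(words) == 0:
        raise ValueError("no scorable words")
    carriers = effective_affect_tokens(words, lexicon, antonyms)
    n = len(carriers)
    m = {emo: 0 for emo in EMOTIONS}
    for tok in carriers:
        for emo in tok.emotions:
            m[emo] += 1
    r = {emo: m[emo] / n for emo in EMOTIONS}
    return EmotionProfile(r=r, m=m, n=n)


@dataclass(frozen=True)
class ZScoreProfile:
    r_target: Mapping[str, float]
    null_mean: Mapping[str, float]
    null_sd: Mapping[str, float]
    z: Mapping[str, float]  # NaN where the null has zero variance
    significant: Mapping[str, bool]
    n_samples: int
    sample_size: int
    threshold: float = Z_THRESHOLD

    def as_dict(self) -> dict:
        return {
            emo: {
                "r_target": self.r_target[emo],
                "null_mean": self.null_mean[emo],
                "null_sd": self.null_sd[emo],
                "z": self.z[emo],
                "significant": self.significant[emo],
            }
            for emo in EMOTIONS
        }


def profile_zscores(
    target_words: Sequence[str],
    pool_words: Sequence[str],
    lexicon: AffectLexicon,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
    antonyms: Mapping[str, Sequence[str]] | None = None,
) -> ZScoreProfile:
    """Z-scores of a target profile against random same-size pool samples.

    Each of *n_samples* baseline profiles is built from ``len(target)``
    words drawn without replacement from *pool_words*; for each emotion
    z = (r_target − mean(r_null)) / sd(r_null). Emotions whose resampled
    richness has zero variance get z = NaN (flagged, not infinite).
    """
    size = len(target_words)
    pool = list(pool_words)
    if size == 0:
        raise ValueError("empty target")
    if len(pool) < size:
        raise ValueError("pool smaller than the target sample size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    target = emotional_richness(target_words, lexicon, antonyms)

    # Indicator matrix over the pool: one richness evaluation per sample is
    # a mean of rows. Negations are not resolved inside the pool (the pool
    # is an unordered word sample, not a text).
    ind = np.zeros((len(pool), len(EMOTIONS)), dtype=np.float64)
    for i, w in enumerate(pool):
        emos = lexicon.emotions_of(w)
        for j, emo in enumerate(EMOTIONS):
            if emo in emos:
                ind[i, j] = 1.0
    null_r = np.empty((n_samples, len(EMOTIONS)))
    for s in range(n_samples):
        idx = rng.choice(len(pool), size=size, replace=False)
        null_r[s] = ind[idx].mean(axis=0)

    mean = null_r.mean(axis=0)
    sd = null_r.std(axis=0, ddof=1)
    z = {}
    for j, emo in enumerate(EMOTIONS):
        z[emo] = float((target.r[emo] - mean[j]) / sd[j]) if sd[j] > 0 else float("nan")
    return ZScoreProfile(
        r_target=dict(target.r),
        null_mean={emo: float(mean[j]) for j, emo in enumerate(EMOTIONS)},
        null_sd={emo: float(sd[j]) for j, emo in enumerate(EMOTIONS)},
        z=z,
        significant={emo: bool(abs(z[emo]) > Z_THRESHOLD) if np.isfinite(z[emo]) else False
                     for emo in EMOTIONS},
        n_samples=n_samples,
        sample_size=size,
    )


def compare_groups_rank(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal–Wallis H test (with tie correction) across ≥ 2 groups.

    Identical pooled values across all groups give (H=0, p=1) rather than
    an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def sentiment_contingency_test(counts) -> tuple[float, float]:
    """Pearson chi-square on a group × {pos, neg, neu} contingency table."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
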