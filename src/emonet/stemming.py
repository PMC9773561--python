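"""Deterministic suffix-stripping stemmer.

A single-pass stripper covering the inflectional suffixes that matter for
collapsing valence-bearing word forms onto one stem ("sad"/"sadness",
"cry"/"crying"). It is intentionally small and fully deterministic; any
callable ``str -> str`` can be supplied in its place throughout the package
(e.g. a Snowball stemmer when available).
"""

from __future__ import annotations

# Longest-first; at most one suffix is stripped per word.
_SUFFIXES = ("ness", "ing", "ed", "es", "ly", "s")
_MIN_STEM = 3


def stem(word: str) -> str:
    """Return the lowercase stem of *word*.

    Strips at most one of ``ness/ing/ed/es/ly/s`` when the remainder keeps
    at least three characters; a trailing ``ss`` is never reduced
    ("bless" stays "bless").
    """
    w = word.lower()
    for suf in _SUFFIXES:
        if w.endswith(suf) and len(w) - len(suf) >= _MIN_STEM:
            if suf == "s" and w.endswith("ss"):
                continue
            return w[: -len(suf)]
    return w
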