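"""Shuffled and Uniform label randomizations with z-score testing.

Both null models hold structure fixed and randomize valence labels only:

* **Shuffled** preserves the empirical label multiset exactly — at list
  level it permutes the order of the words in each list, at network level
  it permutes the one-label-per-node assignment across nodes.
* **Uniform** draws every label independently and uniformly from
  {positive, negative, neutral}, destroying any correlation between valence
  and frequency or position.

Observed statistics (per-list entropies; triangle signature counts and the
complexity degree c) are compared to the ensemble by
z = (observed − mean)/sd with |z| > 1.96 flagging significance at 0.05.
Under the Uniform model the expected complexity of any topology is
E[c] = 1 − (2/3)³·2 + (1/3)³ = 4/9 by inclusion–exclusion, a closed form
the test suite checks against.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .affect_metrics import (
    LABEL_CODES,
    SIGNATURES,
    census_from_codes,
    emotional_entropy,
    triangle_list,
)
from .lexicon import SENTIMENT_LABELS
from .profiling import compare_groups_rank
from .recall_graph import EmotionalWordList

SHUFFLED = "shuffled"
UNIFORM = "uniform"
Z_THRESHOLD = 1.96

_CODE_TO_LABEL = {c: lab for lab, c in LABEL_CODES.items()}


def zscore(observed: float, samples: Sequence[float]) -> float:
    """(observed − mean)/sd of *samples*; NaN when the sd is zero."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples")
    sd = arr.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((observed - arr.mean()) / sd)


@dataclass
class NullEnsemble:
    model: str
    level: str  # "list" or "network"
    n_iter: int
    seed: int | None
    observed: dict[str, float]
    samples: dict[str, np.ndarray]  # statistic -> per-iteration values
    z: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for stat, obs in self.observed.items():
            self.z[stat] = zscore(obs, self.samples[stat])
            self.significant[stat] = (
                bool(abs(self.z[stat]) > Z_THRESHOLD)
                if math.isfinite(self.z[stat])
                else False
            )

    def summary(self) -> dict:
        return {
            "model": self.model,
            "level": self.level,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "statistics": {
                stat: {
                    "observed": self.observed[stat],
                    "null_mean": float(np.mean(self.samples[stat])),
                    "null_sd": float(np.std(self.samples[stat], ddof=1)),
                    "z": self.z[stat],
                    "significant": self.significant[stat],
                }
                for stat in self.observed
            },
        }


def _check_model(model: str) -> None:
    if model not in (SHUFFLED, UNIFORM):
        raise ValueError(f"unknown null model {model!r}")


def list_null(
    lists: Sequence[EmotionalWordList],
    model: str,
    n_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> NullEnsemble:
    """Entropy ensemble under list-level randomization.

    Per iteration every list is randomized (labels permuted, or redrawn
    uniformly) and its entropy recomputed; the ensemble records the median
    and mean per-list entropy of each iteration, plus the full entropy
    matrix in ``samples["entropy_matrix"]`` (n_iter × n_lists).
    """
    _check_model(model)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    usable = [l for l in lists if len(l) >= 2]
    if not usable:
        raise ValueError("no lists with at least 2 stems")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = [np.array([LABEL_CODES[v] for v in l.valence_seq], dtype=np.int8)
            for l in usable]

    observed_h = np.array(
        [emotional_entropy(l.valence_seq).h for l in usable]
    )

    h_matrix = np.empty((n_iter, len(seqs)))
    for it in range(n_iter):
        for j, codes in enumerate(seqs):
            if model == SHUFFLED:
                rnd = rng.permutation(codes)
            else:
                rnd = rng.integers(0, 3, size=codes.size)
            diff = np.count_nonzero(rnd[1:] != rnd[:-1])
            h_matrix[it, j] = _binary_entropy(diff / (codes.size - 1))

    ens = NullEnsemble(
        model=model,
        level="list",
        n_iter=n_iter,
        seed=seed if isinstance(seed, int) else None,
        observed={
            "median_entropy": float(np.median(observed_h)),
            "mean_entropy": float(np.mean(observed_h)),
        },
        samples={
            "median_entropy": np.median(h_matrix, axis=1),
            "mean_entropy": h_matrix.mean(axis=1),
        },
    )
    ens.samples["entropy_matrix"] = h_matrix
    ens.samples["observed_entropies"] = observed_h
    return ens


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def network_null(
    g: nx.Graph,
    model: str,
    n_iter: int = 500,
    seed: int | np.random.Generator | None = None,
    keep_labels: bool = False,
) -> NullEnsemble:
    """Triad-census ensemble under node-label randomization.

    Topology is never touched: the triangle list is computed once and only
    node labels change per iteration. Statistics are the 10 signature
    counts and the complexity degree c; with *keep_labels* the per-iteration
    label code matrix is stored in ``samples["labels"]`` (for conservation
    checks).
    """
    _check_model(model)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    nodes = list(g.nodes)
    labels = []
    for n in nodes:
        lab = g.nodes[n].get("sentiment_label")
        if lab not in SENTIMENT_LABELS:
            raise ValueError(f"node {n!r} has no valid valence label")
        labels.append(LABEL_CODES[lab])
    codes = np.array(labels, dtype=np.int8)
    index = {n: i for i, n in enumerate(nodes)}
    tris = triangle_list(g)
    if not tris:
        raise ValueError("no triads: the network has no triangles")
    tri_idx = np.array([[index[a], index[b], index[c]] for a, b, c in tris])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs_counts, obs_inc = census_from_codes(codes[tri_idx])
    n_tri = len(tris)

    sig_samples = np.zeros((n_iter, len(SIGNATURES)))
    c_samples = np.empty(n_iter)
    label_hist = np.empty((n_iter, codes.size), dtype=np.int8) if keep_labels else None
    for it in range(n_iter):
        if model == SHUFFLED:
            rnd = rng.permutation(codes)
        else:
            rnd = rng.integers(0, 3, size=codes.size).astype(np.int8)
        if keep_labels:
            label_hist[it] = rnd
        counts, n_inc = census_from_codes(rnd[tri_idx])
        for j, sig in enumerate(SIGNATURES):
            sig_samples[it, j] = counts.get(sig, 0)
        c_samples[it] = n_inc / n_tri

    observed = {sig: float(obs_counts.get(sig, 0)) for sig in SIGNATURES}
    observed["c"] = obs_inc / n_tri
    samples = {sig: sig_samples[:, j] for j, sig in enumerate(SIGNATURES)}
    samples["c"] = c_samples
    ens = NullEnsemble(
        model=model,
        level="network",
        n_iter=n_iter,
        seed=seed if isinstance(seed, int) else None,
        observed=observed,
        samples=samples,
    )
    if keep_labels:
        ens.samples["labels"] = label_hist
        ens.samples["observed_labels"] = codes
    return ens


def compare_ensembles(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Kruskal–Wallis comparison of two statistic samples (e.g. observed
    per-list entropies vs a null ensemble)."""
    return compare_groups_rank(sample_a, sample_b)
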