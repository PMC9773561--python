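"""End-to-end orchestration of the two studies.

Study 1 works on word-word co-occurrence networks built from whole notes
and from their final sentences: closeness prominence of the "last words",
sentiment contingency, and the 8-emotion z-profile of last words against
resampled non-last words.

Study 2 works on emotional word lists and their windowed co-occurrence
networks: per-list entropies, ordered triad counts, triangle censuses with
the complexity degree c, and the Shuffled/Uniform null-model families at
both list and network level.

All randomness flows from one top-level seed through
``numpy.random.SeedSequence`` substreams, so reports are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import affect_metrics, null_models, profiling, recall_graph, text_graph
from .lexicon import NEGATIVE, NEUTRAL, POSITIVE, AffectLexicon
from .recall_graph import EmotionalWordList
from .text_graph import ALL_SENTENCES, LAST_SENTENCES, NoteCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and sizes for a full run; defaults are the study values."""

    min_sentences: int = 2
    min_list_length: int = 5
    window: int = 2
    min_count: int = 2
    alpha: float = 0.05
    n_samples: int = 1000
    n_iter: int = 500
    seed: int | None = None

    def __post_init__(self):
        for name in ("min_sentences", "min_list_length", "window",
                     "min_count", "n_samples", "n_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _substreams(seed: int | None, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_study1(
    corpus: NoteCorpus,
    lexicon: AffectLexicon,
    config: RunConfig = RunConfig(),
    antonyms: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Prominence and emotional content of last words.

    Builds the all-sentence and last-sentence co-occurrence networks,
    compares last-word closeness against all other words (Kruskal–Wallis),
    tests the sentiment-label contingency between the two word groups
    (chi-square), and profiles last-word emotions against random samples of
    non-last words drawn from the largest connected component (stopwords
    excluded from the pool).
    """
    (rng_profile,) = _substreams(config.seed, 1)

    g_all = text_graph.build_cooccurrence_network(corpus, ALL_SENTENCES, lexicon)
    g_last = text_graph.build_cooccurrence_network(corpus, LAST_SENTENCES, lexicon)
    close = text_graph.closeness(g_all)
    lw = text_graph.last_words(corpus)

    lw_in = sorted(w for w in lw if w in g_all)
    others = sorted(set(g_all.nodes) - set(lw_in))
    close_last = [close[w] for w in lw_in]
    close_other = [close[w] for w in others]
    h_stat, h_p = profiling.compare_groups_rank(close_last, close_other)

    def _label_counts(words):
        c = Counter(g_all.nodes[w]["sentiment_label"] for w in words)
        return [c[POSITIVE], c[NEGATIVE], c[NEUTRAL]]

    chi2, chi2_p = profiling.sentiment_contingency_test(
        [_label_counts(lw_in), _label_counts(others)]
    )

    # Sampling pool: largest connected component, stopwords out, last words out.
    lcc = max(nx.connected_components(g_all), key=len)
    pool = sorted(
        w for w in lcc
        if w not in lw and not corpus.is_stopword(w) and not corpus.is_name_placeholder(w)
    )
    zprofile = profiling.profile_zscores(
        lw_in, pool, lexicon, n_samples=config.n_samples, seed=rng_profile,
        antonyms=antonyms,
    )

    tau = text_graph.edge_valence_homophily(g_all)
    return {
        "study": 1,
        "config": asdict(config),
        "networks": {
            "all_sentences": {"nodes": g_all.number_of_nodes(),
                              "edges": g_all.number_of_edges()},
            "last_sentences": {"nodes": g_last.number_of_nodes(),
                               "edges": g_last.number_of_edges()},
        },
        "label_counts_all": dict(Counter(
            g_all.nodes[w]["sentiment_label"] for w in g_all.nodes)),
        "homophily": {"kendall_tau": tau.kendall_tau, "p_value": tau.p_value,
                      "defined": tau.defined},
        "n_last_words": len(lw),
        "closeness_test": {"H": h_stat, "p": h_p,
                           "mean_last": float(np.mean(close_last)),
                           "mean_other": float(np.mean(close_other))},
        "sentiment_contingency": {"chi2": chi2, "p": chi2_p},
        "emotion_zscores": zprofile.as_dict(),
    }


def _census_payload(census: affect_metrics.TriadCensus) -> dict:
    return {
        "counts": dict(census.counts),
        "n_coherent": census.n_coherent,
        "n_incoherent": census.n_incoherent,
        "c": census.c,
        "c_defined": census.c is not None,
    }


def _list_level_payload(lists: Sequence[EmotionalWordList]) -> dict:
    entropies = {
        l.source_id: affect_metrics.emotional_entropy(l.valence_seq).h
        for l in lists if len(l) >= 2
    }
    ordered: Counter = Counter()
    per_list_census = Counter()
    for l in lists:
        ordered.update(affect_metrics.ordered_triad_counts(l.valence_seq))
    for triple, cnt in ordered.items():
        kind = affect_metrics.classify_triad(
            [{"+": POSITIVE, "-": NEGATIVE, "n": NEUTRAL}[s] for s in triple]
        )
        per_list_census[kind] += cnt
    return {
        "n_lists": len(lists),
        "entropies": entropies,
        "ordered_triads": {"".join(k): v for k, v in ordered.items()},
        "individual_coherent": per_list_census["coherent"],
        "individual_incoherent": per_list_census["incoherent"],
    }


def run_study2(
    note_lists: Sequence[EmotionalWordList],
    recall_lists: Sequence[EmotionalWordList],
    config: RunConfig = RunConfig(),
) -> dict:
    """Entropy and complexity of notes vs healthy recalls with all four
    null-model families (list/network × shuffled/uniform) per population."""
    rngs = _substreams(config.seed, 8)
    report: dict = {"study": 2, "config": asdict(config), "populations": {}}

    pops = {"notes": note_lists, "recalls": recall_lists}
    entropy_samples = {}
    for p, (name, lists) in enumerate(pops.items()):
        lists = [l for l in lists if len(l) >= config.min_list_length]
        if not lists:
            raise ValueError(f"population {name!r} has no usable lists")
        payload = _list_level_payload(lists)
        entropy_samples[name] = list(payload["entropies"].values())

        g = recall_graph.build_recall_network(
            lists, a=config.window, min_count=config.min_count, alpha=config.alpha
        )
        network = {"nodes": g.number_of_nodes(), "edges": g.number_of_edges()}
        nulls = {}
        try:
            census = affect_metrics.triad_census(g)
            network["census"] = _census_payload(census)
            has_triangles = census.n_triangles > 0
        except ValueError:
            has_triangles = False
        if not has_triangles:
            network["census"] = {"c": None, "c_defined": False}
        for m, model in enumerate((null_models.SHUFFLED, null_models.UNIFORM)):
            ens_list = null_models.list_null(
                lists, model, n_iter=config.n_iter, seed=rngs[4 * m + 2 * p]
            )
            nulls[f"list_{model}"] = ens_list.summary()
            nulls[f"list_{model}"]["entropy_vs_null_KW"] = _kw_payload(
                entropy_samples[name], ens_list.samples["entropy_matrix"].ravel()
            )
            if has_triangles:
                ens_net = null_models.network_null(
                    g, model, n_iter=config.n_iter, seed=rngs[4 * m + 2 * p + 1]
                )
                nulls[f"network_{model}"] = ens_net.summary()
        report["populations"][name] = {
            "lists": {k: v for k, v in payload.items() if k != "entropies"},
            "median_entropy": float(np.median(entropy_samples[name])),
            "network": network,
            "null_models": nulls,
        }

    k, pv = profiling.compare_groups_rank(
        entropy_samples["notes"], entropy_samples["recalls"]
    )
    report["entropy_comparison"] = {"K": float(k), "p": float(pv)}
    c_notes = report["populations"]["notes"]["network"]["census"].get("c")
    c_recalls = report["populations"]["recalls"]["network"]["census"].get("c")
    report["complexity_comparison"] = {
        "c_notes": c_notes,
        "c_recalls": c_recalls,
        "gap": (c_notes - c_recalls)
        if c_notes is not None and c_recalls is not None else None,
    }
    return report


def _kw_payload(a, b) -> dict:
    k, p = profiling.compare_groups_rank(a, b)
    return {"K": float(k), "p": float(p)}


def write_report(report: dict, out_dir: str | Path, name: str = "report.json") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonify))
    logger.info("report written to %s", path)
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
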