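# emonet

Cognitive-network analysis of emotional narratives: how short, affect-laden
texts — farewell notes, emotional-recall (fluency task) responses — organize
positive, negative and neutral states, and whether that organization differs
from chance and between populations.

The package is aimed at computational psycholinguists and mental-health text
researchers. Because the primary corpora in this area are sensitive and not
redistributable, a first-class synthetic generator reproduces their
statistical shape (note lengths, valence mixes, fluency-list structure) so
the entire pipeline is developed, tested and demonstrated offline; real
corpora and lexicon files drop in via the same CSV/TSV interfaces.

## What it computes

* **Word co-occurrence networks** — two words are linked when one
  immediately follows the other in at least one sentence. Node prominence is
  closeness centrality, `C_i = (N−1) / Σ_j d_ij` within a connected
  component; edge-valence homophily is the Kendall tau-b `κ_t` between the
  sentiment labels of linked words.
* **Affect annotation** — a valence lexicon discretized by lexicon-wide
  quartiles (negative ≤ Q1 < neutral < Q3 ≤ positive), an 8-emotion lexicon
  (joy, trust, fear, surprise, sadness, disgust, anger, anticipation), and
  negation resolution to antonyms ("not good" counts as "bad").
* **Emotional profiling** — richness `r_i = m_i/N` per emotion, z-scored
  against same-size random word samples (the data behind "emotional flower"
  plots), with |z| > 1.96 marking the 0.05 level.
* **Emotional entropy** — for an ordered list of emotional words, the
  two-event Shannon entropy (bits) of the same/different indicator between
  adjacent valence labels:
  `h = −p₀ log₂ p₀ − p₁ log₂ p₁`.
* **Emotional complexity** — a node-signed analog of structural balance: a
  triangle of words is *incoherent* iff it mixes positive and negative
  valence, and `c = n_incoherent / (n_coherent + n_incoherent)` over all
  triangles of the emotional network (built from word lists by windowed
  co-occurrence with a binomial link filter).
* **Null models** — Shuffled (label-permuting, frequency-preserving) and
  Uniform (labels iid uniform over three classes) randomizations at list and
  network level, with z-scores per triangle signature and for `c`. Under the
  Uniform model `E[c] = 4/9` for any topology.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from emonet import (GeneratorSpec, gen_lexicon, gen_corpus,
                    extract_emotional_lists, build_recall_network,
                    triad_census, emotional_entropy, network_null, UNIFORM)

rng = np.random.default_rng(42)
spec = GeneratorSpec.suicide_notes(seed=42)     # 52/31/17 valence mix
lexicon, dictionary = gen_lexicon(spec, rng)
corpus = gen_corpus(spec, lexicon, dictionary, rng)

lists = extract_emotional_lists(corpus, dictionary)
h = [emotional_entropy(l.valence_seq).h for l in lists]
g = build_recall_network(lists)                 # window 2, binomial filter
census = triad_census(g)
ens = network_null(g, UNIFORM, n_iter=500, seed=42)
```

This prints (via the obvious `print` statements):

```
139 usable emotional word lists from 139 notes
median emotional entropy: 0.971 bits
emotional network: 166 stems, 341 links
triangles: 298 (187 incoherent), c = 0.628
Uniform null: mean c_r = 0.447, z(c) = 1.40
```

Reading: the synthetic note-like population switches valence often (median
entropy near the 1-bit maximum); its emotional network mixes polarities in
62.8% of its triangles; the Uniform null's mean complexity sits at the 4/9
closed form (0.447), and the observed `c` is 1.4 null standard deviations
above it — not significant at |z| > 1.96 for this seed.

## Command line

```bash
emonet simulate --seed 3 --out data/          # synthetic corpus + lexicons
emonet study1 --corpus data/corpus.csv --valence data/valence.tsv \
       --emotions data/emotions.tsv --seed 4 --out out1/
emonet study2 --corpus data/corpus.csv --dictionary data/dictionary.tsv \
       --recalls data/recalls.csv --seed 5 --out out2/
```

`study1` reports network sizes, `κ_t` homophily, the closeness rank test for
last words, the sentiment contingency test, and the 8-emotion z-profile.
`study2` reports per-list entropies, ordered triad counts, triangle censuses
with `c` for both populations, all four null-model families, and the
cross-population rank tests. Additional subcommands (`build-network`,
`profile`, `entropy`, `complexity`, `nulls`) expose the individual stages.

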