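# Methods

`emonet` analyses how short emotional narratives (farewell notes, fluency-task
recalls) organize positive, negative and neutral affect, using three linked
representations: word co-occurrence networks, ordered emotional word lists,
and windowed co-occurrence networks over emotional stems.

## Affect annotation

Every word carries a continuous valence score. Sentiment labels discretize the
lexicon-wide score distribution: words at or below the first quartile are
*negative*, at or above the third quartile *positive*, otherwise *neutral*.
Quartiles use inclusive linear interpolation (`numpy.quantile`, default
method). Boundary ties are treated as extreme (≤ Q1 negative, ≥ Q3 positive);
when the distribution is so concentrated that Q1 = Q3 the comparisons become
strict, so an all-equal lexicon is entirely neutral and a concentrated one
labels only its outliers. This rule guarantees that the three labels always
partition the lexicon and that raising a single word's score never moves its
label toward negative.

Emotion annotation is a word → subset map over the eight basic emotions (joy,
trust, fear, surprise, sadness, disgust, anger, anticipation); a word may
elicit several emotions or none.

Negations flip affect rather than being dropped: a marker from
{not, no, never, n't, cannot, without} scopes over the single following token,
which is replaced for counting purposes by an antonym. When several antonyms
exist, the lexicographically first one present in the valence lexicon is used
(deterministic and auditable); when none is usable the token is kept with its
sentiment label inverted (positive↔negative; neutral unchanged), so the
flipped affect still enters the counts. The one-token scope matches the
adjacent-bigram network model.

## Word co-occurrence networks (Study 1)

Notes are tokenized (lowercase; sentences split at `.!?`; tokens keep
intra-word apostrophes and underscores, the latter so anonymized placeholders
like `name_anna` survive whole). Notes with fewer than two sentences are
dropped at load. Two words are linked when one immediately follows the other
inside at least one sentence; the graph is simple (bigram multiplicity is
stored as an edge weight, adjacent self-repetition creates no self-loop) and
stopwords and pronouns remain as nodes. All Study-1 statistics use the
unweighted topology.

Prominence is closeness centrality, C_i = (N−1)/Σ_j d_ij, computed within each
connected component (singletons get 0; cross-component distances are never
summed). Edge-valence homophily is Kendall tau-b over the edge endpoint labels
mapped to {−1, 0, +1}, with both orientations of every undirected edge
included so the statistic is orientation-invariant.

"Last words" are the union over notes of the final sentence's tokens, minus
stopwords and name placeholders, with set semantics. Their 8-emotion richness
profile (r_i = m_i/N, where every token counts toward N whether or not the
emotion lexicon knows it) is z-scored against 1,000 same-size samples drawn
without replacement from the largest connected component of the full network,
stopwords excluded. An emotion whose resampled richness has zero variance gets
an undefined z (NaN), never ±∞. |z| > 1.96 flags the 0.05 level; both signs
are reported, so one-sided readings are available to the caller.

## Emotional word lists and recall networks (Study 2)

A text is reduced to the ordered list of its emotional stems: stem every
token, keep stems in the emotional dictionary, preserve order and duplicates.
Lists with fewer than 5 emotional words are dropped (5 matches the fluency
task's response-count scale). The shipped stemmer is a single-pass suffix
stripper (ness/ing/ed/es/ly/s, remainder ≥ 3 characters, trailing "ss"
protected); any `str -> str` callable can replace it.

Lists become a network by windowed co-occurrence with window a = 2: two stems
co-occur at every positional pair within distance ≤ 2 inside a list (windows
never cross lists; a stem never pairs with itself). Pairs seen at least twice
are candidate links, retained when their count k beats a one-sided binomial
tail at α = 0.05: P(X ≥ k) with X ~ Binomial(T, f_u·f_v), where T is the total
number of within-window positional pairs and f the empirical stem frequencies.
The pair-rate convention is configurable (`pair_rate="unordered"` uses
2·f_u·f_v) because published descriptions of this construction differ in what
counts as a trial; the default is the plain product.

## Entropy and complexity

**Emotional entropy** of an ordered list is the two-event Shannon entropy
(base 2, 0·log 0 := 0) of the same/different indicator string between
adjacent valence labels. It lies in [0, 1], is invariant under a global
polarity flip, and distinguishes scattered switching (high h) from bunched
switching (low h) at equal switch counts.

**Emotional complexity** is a node-signed analog of structural balance: a
closed triangle of words is *incoherent* when its three labels include at
least one positive and one negative word (neutral raises no contrast), and
c = n_incoherent / (n_coherent + n_incoherent) over all triangles. Each
unordered node triple is counted once; a graph without triangles has c
undefined (flagged, not zero). Separately, *ordered* triads count sliding
windows of three consecutive labels in a list, so fixed-order patterns like
(+, −, +) are well defined; the unordered census and the ordered counts are
never mixed.

## Null models

Both nulls hold structure fixed and randomize labels only:

* **Shuffled** — permute the labels (the order of words within each list, or
  the one-label-per-node assignment across the network). The label multiset
  is conserved exactly in every iteration.
* **Uniform** — draw each label independently and uniformly over the three
  classes, destroying valence–frequency and valence–position correlations.
  Under this model every triangle is incoherent with probability
  1 − 2·(2/3)³ + (1/3)³ = 4/9 (inclusion–exclusion), so E[c] = 4/9 for any
  topology — a closed form the test suite checks at 500 iterations against
  three Monte-Carlo standard errors.

Defaults are 500 iterations at both levels. Observed statistics (per-list
median/mean entropy; the 10 signature counts and c) are z-scored against the
ensemble; zero-variance statistics are flagged undefined. List-level
comparisons use the per-list entropy samples and Kruskal–Wallis rank tests;
per-signature z-scores are reported alongside the ensemble-level c because
signature counts under the Shuffled model are not independent — c, not any
covariance correction, is the aggregate answer to that dependence.

## Synthetic data

The generator emulates the statistical shape of the study's (sensitive,
unshippable) corpora so every stage runs offline:

* **Lexicon** — 5,000 pseudo-words (CV-syllable strings that are fixed points
  of the stemmer) at 1,250/2,500/1,250 negative/neutral/positive, with scores
  constructed so the quartile rule recovers those class sizes *exactly*
  (boundary scores are tied where needed; class sizes below the quartile mass
  are infeasible under the labeling rule and raise). Emotions are assigned by
  per-class coin flips (positive words skew joy/trust/anticipation, negative
  words fear/sadness/anger/disgust). The emotional dictionary is a uniform
  475-stem sample.
* **Valence dynamics** — a first-order Markov chain over the three classes,
  P = ρ·I + (1−ρ)·π with stay-boost ρ = 0.15: the stationary mix is exactly
  the target π (52/31/17 for the note-like population, 48/22/30 for the
  recall-like one) and ρ produces the weak positive edge-valence homophily
  (κ_t of a few hundredths) seen in such corpora. A first-order chain is the
  minimal mechanism spanning coherent runs and frequent switching;
  higher-order structure is deliberately out of scope.
* **Word choice** — Zipf(s = 1.3) within each class. Emotional vocabulary use
  is heavy-tailed; uniform choice over 475 stems would leave the
  min-count-2 filter with almost no repeated co-occurrences at these corpus
  sizes, whereas s = 1.3 reproduces the scale of the real networks this
  pipeline targets (an emotional network of a few hundred triangles from
  ~139 notes).
* **Corpus shape** — 139 notes of ~120 tokens (SD 30), sentences ~12 tokens,
  final sentences Normal(16, 2) truncated at ≥ 3; stopwords interleaved at
  rate 0.35, dictionary words at rate 0.3 of content tokens, negation markers
  at 0.02, inflected forms (base+s/ed/ing/ness) at 0.2 so stemming is
  exercised. 200 recall lists of exactly 10 distinct stems; screening scores
  are 0 with probability 0.5 (the "healthy" filter), else 1 + Poisson(3).

What the generator does **not** emulate: real syntax or semantics (content
words are pseudo-words), topic structure, position effects within notes,
subjective valence variation, or item-level screening responses. Passing
tests therefore demonstrate that the *pipeline* recovers planted statistical
structure (valence mixes, transition rates, complexity gaps) — not that the
substantive findings generalize to any real corpus.

## Numerical and design choices

* Randomness: every run consumes one top-level seed through
  `numpy.random.SeedSequence` substreams; identical seeds give bit-identical
  reports.
* z-scores use the sample standard deviation (ddof = 1); undefined z (sd = 0)
  propagates as NaN with `significant = False`.
* Kruskal–Wallis uses tie correction; the degenerate all-identical case
  returns (H = 0, p = 1) by definition rather than an error.
* Degenerate inputs are errors, not silent zeros: empty lexicons, sequences
  without transitions, triangle-free graphs passed to the network null,
  unlabeled nodes inside triangles (named in the message).
* Problem sizes in the test suite are scaled to the method, not the corpus:
  oracle checks use ≤ 12-node graphs and ≤ 12-stem lists (100 randomized
  instances per primitive), calibration checks use 200 repeated experiments
  at 250–300 resamples/iterations, and the population-gap check uses 50
  paired full-size synthetic runs.

## Known limitations

* The quartile convention and tie rule are one defensible reading; published
  label splits from other pipelines may use different quantile estimators.
* The binomial link filter's trial definition follows the contract stated
  above; alternative readings of the original fluency-network construction
  are swappable via `pair_rate` but not reproduced in detail.
* Complexity looks at triangles only; longer cycles and other motifs are out
  of scope, as is any individual-level clinical inference — all comparisons
  are group-level.
* The antonym fallback (label inversion) is a pragmatic stand-in when no
  antonym is available; it preserves the intended affect flip but not lexical
  identity.
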