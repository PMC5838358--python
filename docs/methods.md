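# Methods

## The model

`streetlex` rests on the distributional hypothesis: words occurring in
similar contexts tend to have similar meanings. A continuous-bag-of-words
(CBOW) model assigns each vocabulary token a vector by learning to
predict a center token from the arithmetic mean of its context-window
vectors; cosine similarity between the learned (input-side) vectors is
then a proxy for semantic relatedness. Slang discovery is cast as seeded
lexicon expansion: rank the entire vocabulary by cosine similarity to
one or two prototypical slang seeds for the target substance and keep
everything above a threshold chosen to maximize F₂ against an
expert-provided gold lexicon.

## Pipeline stages and the parameters that matter

**Normalization/tokenization.** User handles (`@` + word characters) and
URLs (scheme- or `www.`-prefixed non-space runs) are removed; everything
is lowercased; hashtags, emoticons and emoji are retained. The tokenizer
is tweet-aware and hand-written over stdlib `re`: hashtags and emoticons
are single tokens, and each emoji codepoint (with its variation
selectors / ZWJ-joined continuation) is its own token. Emoji
segmentation matters: a two-emoji run becomes an adjacent bigram, which
is the only mechanism by which an emoji pair can enter the vocabulary as
a single (phrase-merged) term. Case policy and emoji segmentation are
genuinely open choices here; both are fixed as above and exercised by
tests.

**Phrase merging.** Adjacent bigrams scored by
`(count(a,b) − δ) · N / (count(a)·count(b))` with discount δ = 5 and
acceptance threshold 10 (both config-exposed; values follow the standard
reference implementation of this scoring rule). Merging is a single
greedy left-to-right pass, earlier pair wins on overlap, bigrams only —
every attested multiword drug term in the reference tables is two words,
so no trigram pass is performed.

**CBOW training.** From-scratch implementation (numba kernel): negative
sampling with k = 5 noise draws from the unigram^0.75 distribution,
dynamic window (uniform 1..W per center), per-occurrence frequency
subsampling at threshold 1e-3, 5 epochs, learning rate decaying linearly
from 0.025 to 1e-4 of its start. Tokens below `min_count` (default 10)
are dropped entirely, not replaced by a placeholder, so the effective
context window closes over gaps. Training is single-threaded with an
explicit xorshift RNG: a fixed seed reproduces vectors bit for bit. All
hyperparameters sit in `TrainingConfig`; headline defaults are window 5,
dimension 200, min count 10. Similarity always uses input vectors.

**Retrieval.** Four query conditions: each seed term alone, the set
union of both single-term results (ranked by max cosine — the union
*set* is well-defined either way; max preserves the nesting property and
yields a deterministic rank), and the cosine against the unweighted mean
of the two raw seed vectors ("simple mean" taken literally). Seed terms
remain on their own candidate lists (cosine 1.0) unless explicitly
dropped; ties break lexicographically so output files are reproducible.

**Threshold optimization.** Grid 0.01…1.00, step 0.01. Precision counts
each list entry independently by default (spelling variants are distinct
entries, which slightly inflates list size but matches how candidate
lists are produced); a variant-collapsed precision is a switch. Recall
counts a gold term as found if the term or any listed variant appears.
F₂ ties break toward the higher threshold (smaller list, higher
precision at equal F₂). Precision on an empty list is defined as 0 so
the objective is total on the grid.

**Evaluation.** Drug relevancy = mean of the two annotators' hit
proportions on a seeded uniform sample of up to 200 documents containing
the term (all of them when fewer). Percentages are reported to 1 decimal
place, rounded half-up — required to reproduce the reference tables
(84.375 → 84.4). Cohen's κ uses the two annotators' own marginals for
chance agreement. Novel-term extraction removes expert-listed terms and
their variants, then known-technical terms, then collapses the remainder
into spelling-variant groups: an explicit variants file wins over the
built-in heuristic (terms identical after squeezing repeated characters,
e.g. gass/gasss). The known-technical list ships as an editable fixture
since "technical, therefore known" is an annotator judgment, not a
computable property.

## The synthetic generator

Real training data (10⁸-token scale social-media text) is not
redistributable, so the generator emulates what the method exploits:
documents of mean length 10.7 tokens (the tokens-per-tweet ratio of the
motivating corpus); a Zipf(1.1) background vocabulary; topical context
clusters disjoint from the background; a planted synonym set for the
target topic (the "slang"); polysemous terms shared between target and
distractor topics whose target-sense share — the exact analog of drug
relevancy — is controlled by per-topic emission weights and realized
per emission; and planted bigrams (slot terms containing a space)
standing in for multiword strain names. Ground truth records every slot
emission by topic, so realized relevancy is exact, not estimated.

Default study conditions (`default_config`): 200k documents (~2.1M
tokens), three topics (target 0.15, distractor 0.15, pure-background
chatter 0.70), slot rate 0.22 and context rate 0.45 within topical
documents, 12 single-sense synonyms (incl. two bigrams) and four
polysemous terms with expected relevancies ≈ 0.73, 0.28, 0.07, 0.05 —
straddling the 0.25/0.10 bands used by the separation property.

What the generator does **not** model — and therefore what passing tests
do not show about real data: syntax and word order beyond bag-of-context
structure, hashtag pragmatics, orthographic variant clouds, bursty user
behavior, topic correlation. One consequence is worth flagging: within a
topic every context and slot token shares the *same* context
distribution, so the planted cluster is mutually near-cosine-1 and the
identity of a synonym's single nearest neighbor inside that cluster is
tie-breaking noise. Cross-implementation agreement is therefore asserted
at the cluster level (both trainers put each synonym's nearest neighbor
inside the planted cluster), with exact nearest-neighbor identity
required only for the polysemous terms, whose geometry is distinctive.
Real corpora are not tie-degenerate in this way.

## Numerical and design notes

- Vectors are float32; the word2vec text format is written with full
  `repr` so save/load round-trips are bit-exact.
- The sigmoid is clamped at |z| = 6 in the trainer (standard practice;
  gradients vanish beyond that anyway).
- Vocabulary ids are dense, ordered by descending frequency then token,
  making the negative-sampling table layout deterministic.
- Thresholds outside [−1, 1] are permitted at retrieval: > 1 yields an
  empty list (used by tests), < −1 the whole vocabulary.
- Degenerate inputs error early with specific messages: empty corpus,
  empty vocabulary after min-count filtering, no trainable
  (context, center) pair, zero vectors in cosine, κ with chance
  agreement 1, correlation with a zero-variance annotator.
- Problem sizes in the test suite: unit tests run on 1k-document
  corpora; training-quality properties on 20k documents; the end-to-end
  recovery and separation properties on the full 200k-document study
  conditions with dimension 50 and 5 epochs. The pure-numpy reference
  CBOW cross-check trains on the 20k-document corpus, where it is the
  slowest single step (~70 s).

## Known limitations

- Precision of the candidate list is intrinsically modest: topically
  related non-synonyms (context/paraphernalia analogs) are genuinely
  distributionally similar and are retrieved alongside synonyms. The
  method is a recall-oriented screen ahead of human review, and β = 2
  encodes exactly that.
- Terms used in the target sense in ≲ 20% of their occurrences sit
  closer to their dominant sense's cluster and fall below any workable
  threshold — the central failure mode on real data, reproduced in
  miniature by the low-relevancy planted terms.
- Single-pass bigram merging cannot form trigrams or longer phrases.
- The trainer is single-threaded by design (determinism over speed);
  corpus scale beyond ~10⁸ tokens would need sharded training and is out
  of scope.
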