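"""Collocation detection and phrase merging.

Multiword slang ("sour diesel", "jazz cabbage") must enter the embedding
vocabulary as single tokens or it cannot be retrieved as a term. Adjacent
bigrams whose discounted association score

    score(a, b) = (count(a,b) - delta) * N / (count(a) * count(b))

exceeds a threshold are merged left-to-right into ``a_b`` tokens in a
single pass (bigrams only; all attested multiword drug terms are two
words). ``delta`` discounts rare accidental co-occurrences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Set, Tuple

from .preprocess import TokenizedCorpus

__all__ = [
    "BigramStatistics",
    "PhraseModel",
    "count_ngrams",
    "score_bigram",
    "build_phrase_model",
    "merge_phrases",
    "save_phrase_model",
    "load_phrase_model",
]

DEFAULT_DISCOUNT = 5.0
DEFAULT_THRESHOLD = 10.0
DELIMITER = "_"


@dataclass
class BigramStatistics:
    """Exact unigram and adjacent-bigram counts over a tokenized corpus."""

    unigram_counts: Counter
    bigram_counts: Counter
    total_tokens: int


@dataclass
class PhraseModel:
    """Accepted bigrams plus the scoring parameters that produced them."""

    accepted_bigrams: Set[Tuple[str, str]]
    delimiter: str = DELIMITER
    discount: float = DEFAULT_DISCOUNT
    score_threshold: float = DEFAULT_THRESHOLD
    scores: Dict[Tuple[str, str], float] = field(default_factory=dict)
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)


def count_ngrams(corpus: TokenizedCorpus) -> BigramStatistics:
    """Count unigrams and adjacent bigrams; bigrams never span documents."""
    if not any(len(doc) for doc in corpus):
        raise ValueError("corpus contains no tokens")
    unigrams: Counter = Counter()
    bigrams: Counter = Counter()
    total = 0
    for doc in corpus:
        unigrams.update(doc)
        total += len(doc)
        bigrams.update(zip(doc, doc[1:]))
    return BigramStatistics(unigrams, bigrams, total)


def score_bigram(stats: BigramStatistics, a: str, b: str, delta: float = DEFAULT_DISCOUNT) -> float:
    """Discounted association score; negative when count(a,b) <= delta."""
    ca = stats.unigram_counts.get(a, 0)
    cb = stats.unigram_counts.get(b, 0)
    if ca == 0 or cb == 0:
        missing = a if ca == 0 else b
        raise KeyError(f"unknown token in bigram: {missing!r}")
    cab = stats.bigram_counts.get((a, b), 0)
    return (cab - delta) * stats.total_tokens / (ca * cb)


def build_phrase_model(
    corpus: TokenizedCorpus,
    delta: float = DEFAULT_DISCOUNT,
    score_threshold: float = DEFAULT_THRESHOLD,
    delimiter: str = DELIMITER,
    min_count: int = 1,
) -> PhraseModel:
    """Score every observed bigram and accept those above the threshold."""
    stats = count_ngrams(corpus)
    accepted: Set[Tuple[str, str]] = set()
    scores: Dict[Tuple[str, str], float] = {}
    counts: Dict[Tuple[str, str], int] = {}
    for (a, b), cab in stats.bigram_counts.items():
        if cab < min_count:
            continue
        s = score_bigram(stats, a, b, delta)
        if s > score_threshold:
            accepted.add((a, b))
            scores[(a, b)] = s
            counts[(a, b)] = cab
    return PhraseModel(accepted, delimiter, delta, score_threshold, scores, counts)


def merge_phrases(corpus: TokenizedCorpus, model: PhraseModel) -> TokenizedCorpus:
    """Greedy left-to-right, non-overlapping merge of accepted bigrams.

    On overlap ([a,b,b] with both (a,b) and (b,b) accepted) the earlier
    pair wins; merging is a single pass, so a merged token never
    participates in a further merge.
    """
    accepted = model.accepted_bigrams
    delim = model.delimiter
    out: TokenizedCorpus = []
    for doc in corpus:
        merged = []
        i = 0
        n = len(doc)
        while i < n:
            if i + 1 < n and (doc[i], doc[i + 1]) in accepted:
                merged.append(doc[i] + delim + doc[i + 1])
                i += 2
            else:
                merged.append(doc[i])
                i += 1
        out.append(merged)
    return out


def save_phrase_model(model: PhraseModel, path: str) -> None:
    """TSV: token_a, token_b, count, score — sorted for reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token_a\ttoken_b\tcount\tscore\n")
        for a, b in sorted(model.accepted_bigrams):
            fh.write(f"{a}\t{b}\t{model.counts.get((a, b), 0)}\t{model.scores.get((a, b), 0.0):.6f}\n")


def load_phrase_model(
    path: str,
    delta: float = DEFAULT_DISCOUNT,
    score_threshold: float = DEFAULT_THRESHOLD,
) -> PhraseModel:
    accepted: Set[Tuple[str, str]] = set()
    scores: Dict[Tuple[str, str], float] = {}
    counts: Dict[Tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("token_a\t"):
            raise ValueError(f"{path}:1: expected phrase-model header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            a, b, cnt, s = parts
            accepted.add((a, b))
            counts[(a, b)] = int(cnt)
            scores[(a, b)] = float(s)
    return PhraseModel(accepted, DELIMITER, delta, score_threshold, scores, counts)
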