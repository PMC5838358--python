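"""Continuous-bag-of-words embeddings with negative sampling, from scratch.

The model maps every retained token type to a dense vector such that
tokens used in similar contexts end up with high cosine similarity — the
distributional signal that lets seed slang terms pull in their synonyms.

Architecture and defaults follow the standard CBOW recipe: predict the
center token from the arithmetic mean of the context vectors within a
dynamic window (uniform 1..W per position), trained by logistic
regression against k noise tokens drawn from the unigram^0.75
distribution, with per-occurrence frequency subsampling and a linearly
decaying learning rate. Training is single-threaded and driven by an
explicit xorshift RNG, so a fixed seed reproduces the vectors bit for
bit.

Similarity always uses the input (context-side) vectors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from numba import njit

from .preprocess import TokenizedCorpus

__all__ = [
    "Vocabulary",
    "TrainingConfig",
    "EmbeddingModel",
    "build_vocabulary",
    "train_cbow",
    "save_model",
    "load_model",
]


@dataclass
class Vocabulary:
    """Dense token->id mapping over tokens meeting the frequency floor."""

    token_to_id: Dict[str, int]
    tokens: List[str]
    counts: np.ndarray  # corpus frequency per id
    min_count: int

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id


@dataclass
class TrainingConfig:
    """CBOW hyperparameters; every random draw is fixed by ``seed``."""

    window: int = 5
    dim: int = 200
    min_count: int = 10
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    subsample: float = 1e-3
    dynamic_window: bool = True
    seed: int = 1

    def validate(self) -> None:
        for name in ("window", "dim", "min_count", "negative", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class EmbeddingModel:
    vocab: Vocabulary
    vectors: np.ndarray  # V x D, float32
    dim: int
    window: int
    _unit: np.ndarray = field(default=None, repr=False)  # cached row-normalized copy

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocab.token_to_id[token]]
        except KeyError:
            raise KeyError(f"token not in vocabulary: {token!r}") from None

    def unit_vectors(self) -> np.ndarray:
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.vectors / norms
        return self._unit


def build_vocabulary(corpus: TokenizedCorpus, min_count: int = 10) -> Vocabulary:
    """Keep tokens with frequency >= min_count; ids are dense, ordered by
    descending frequency then token (ties), matching the negative-sampling
    table layout."""
    freq = Counter()
    for doc in corpus:
        freq.update(doc)
    kept = [(t, c) for t, c in freq.items() if c >= min_count]
    if not kept:
        raise ValueError(f"no token reaches min_count={min_count}; vocabulary empty")
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    tokens = [t for t, _ in kept]
    counts = np.array([c for _, c in kept], dtype=np.float64)
    return Vocabulary({t: i for i, t in enumerate(tokens)}, tokens, counts, min_count)


def _encode(corpus: TokenizedCorpus, vocab: Vocabulary) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten the corpus to vocabulary ids; out-of-vocabulary tokens are
    skipped entirely (no placeholder), shrinking the effective window gap."""
    t2i = vocab.token_to_id
    ids: List[int] = []
    offsets = [0]
    for doc in corpus:
        ids.extend(t2i[t] for t in doc if t in t2i)
        offsets.append(len(ids))
    return np.array(ids, dtype=np.int32), np.array(offsets, dtype=np.int64)


def _noise_table(counts: np.ndarray, size: int = 1 << 20) -> np.ndarray:
    """Negative-sampling lookup table from the unigram^0.75 distribution."""
    p = counts ** 0.75
    p /= p.sum()
    bounds = np.cumsum(p) * size
    table = np.zeros(size, dtype=np.int32)
    idx = 0
    for i in range(size):
        while idx < len(bounds) - 1 and i >= bounds[idx]:
            idx += 1
        table[i] = idx
    return table


@njit(cache=True)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _train_kernel(
    data, offsets, keep_prob, table, syn0, syn1, window, negative,
    epochs, alpha0, dynamic_window, seed,
):  # pragma: no cover - exercised via train_cbow
    V, D = syn0.shape
    tsize = table.shape[0]
    ndocs = offsets.shape[0] - 1
    total_words = data.shape[0] * epochs
    alpha_min = alpha0 * 1e-4
    state = np.uint64(seed * np.uint64(2685821657736338717) + np.uint64(1))
    neu1 = np.zeros(D, dtype=np.float32)
    neu1e = np.zeros(D, dtype=np.float32)
    sent = np.empty(1024, dtype=np.int32)
    words_done = 0
    for _ in range(epochs):
        for d in range(ndocs):
            lo, hi = offsets[d], offsets[d + 1]
            words_done += hi - lo
            # per-occurrence frequency subsampling
            slen = 0
            for i in range(lo, hi):
                w = data[i]
                state = _xorshift(state)
                u = np.float64(state >> np.uint64(11)) / 9007199254740992.0
                if u < keep_prob[w]:
                    if slen < sent.shape[0]:
                        sent[slen] = w
                        slen += 1
            if slen < 2:
                continue
            alpha = alpha0 * (1.0 - words_done / (total_words + 1.0))
            if alpha < alpha_min:
                alpha = alpha_min
            for pos in range(slen):
                center = sent[pos]
                if dynamic_window:
                    state = _xorshift(state)
                    b = np.int64(state % np.uint64(window))
                else:
                    b = np.int64(0)
                w_eff = window - b
                cstart = pos - w_eff
                cend = pos + w_eff
                if cstart < 0:
                    cstart = 0
                if cend >= slen:
                    cend = slen - 1
                cw = 0
                for k in range(D):
                    neu1[k] = 0.0
                for j in range(cstart, cend + 1):
                    if j == pos:
                        continue
                    ctx = sent[j]
                    for k in range(D):
                        neu1[k] += syn0[ctx, k]
                    cw += 1
                if cw == 0:
                    continue
                inv = np.float32(1.0 / cw)
                for k in range(D):
                    neu1[k] *= inv
                    neu1e[k] = 0.0
                # one positive + `negative` noise targets
                for n in range(negative + 1):
                    if n == 0:
                        target = center
                        label = np.float32(1.0)
                    else:
                        state = _xorshift(state)
                        target = table[np.int64(state % np.uint64(tsize))]
                        if target == center:
                            continue
                        label = np.float32(0.0)
                    dot = np.float32(0.0)
                    for k in range(D):
                        dot += neu1[k] * syn1[target, k]
                    if dot > 6.0:
                        pred = np.float32(1.0)
                    elif dot < -6.0:
                        pred = np.float32(0.0)
                    else:
                        pred = np.float32(1.0 / (1.0 + np.exp(-dot)))
                    g = np.float32((label - pred) * alpha)
                    for k in range(D):
                        neu1e[k] += g * syn1[target, k]
                        syn1[target, k] += g * neu1[k]
                for j in range(cstart, cend + 1):
                    if j == pos:
                        continue
                    ctx = sent[j]
                    for k in range(D):
                        syn0[ctx, k] += neu1e[k]


def train_cbow(corpus: TokenizedCorpus, config: TrainingConfig) -> EmbeddingModel:
    """Train CBOW embeddings over a tokenized (phrase-merged) corpus.

    Raises if the vocabulary is empty after frequency filtering or if no
    (context, center) pair can be formed.
    """
    config.validate()
    vocab = build_vocabulary(corpus, config.min_count)
    data, offsets = _encode(corpus, vocab)
    doc_lens = np.diff(offsets)
    if not np.any(doc_lens >= 2):
        raise ValueError("corpus too small: no document yields a (context, center) pair")

    total = vocab.counts.sum()
    if config.subsample > 0:
        f = vocab.counts / total
        keep = np.sqrt(config.subsample / f) + config.subsample / f
        keep_prob = np.minimum(keep, 1.0)
    else:
        keep_prob = np.ones(len(vocab))

    rng = np.random.default_rng(config.seed)
    V, D = len(vocab), config.dim
    syn0 = ((rng.random((V, D), dtype=np.float32) - 0.5) / D).astype(np.float32)
    syn1 = np.zeros((V, D), dtype=np.float32)
    table = _noise_table(vocab.counts)

    _train_kernel(
        data, offsets, keep_prob.astype(np.float64), table, syn0, syn1,
        config.window, config.negative, config.epochs,
        np.float64(config.alpha), config.dynamic_window,
        np.uint64(config.seed % (1 << 63) + 1),
    )
    if not np.all(np.isfinite(syn0)):
        raise FloatingPointError("training produced non-finite vectors")
    return EmbeddingModel(vocab, syn0, D, config.window)


def save_model(model: EmbeddingModel, path: str) -> None:
    """word2vec text format: header ``V D`` then one token + D reals per line.

    Floats are written with full repr so save/load round-trips bit-exactly
    at float32 precision.
    """
    V, D = model.vectors.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{V} {D}\n")
        for i, tok in enumerate(model.vocab.tokens):
            row = " ".join(repr(float(x)) for x in model.vectors[i])
            fh.write(f"{tok} {row}\n")


def load_model(path: str) -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'V D'")
        try:
            V, D = int(header[0]), int(header[1])
        except ValueError:
            raise ValueError(f"{path}:1: non-integer header 'V D'") from None
        tokens: List[str] = []
        vectors = np.empty((V, D), dtype=np.float32)
        for i in range(V):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}:{i + 2}: expected {V} vector lines, got {i}")
            parts = line.rstrip("\n").split(" ")
            if len(parts) != D + 1:
                raise ValueError(f"{path}:{i + 2}: expected token + {D} values")
            tokens.append(parts[0])
            vectors[i] = [float(x) for x in parts[1:]]
        if fh.readline().strip():
            raise ValueError(f"{path}:{V + 2}: trailing content after {V} vectors")
    counts = np.zeros(V, dtype=np.float64)
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, tokens, counts, 0)
    return EmbeddingModel(vocab, vectors, D, 0)
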