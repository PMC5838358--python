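"""Candidate-term retrieval by cosine similarity to seed query terms.

Given a trained embedding model and one or two seed slang terms for the
target substance, rank the whole vocabulary by cosine similarity and keep
everything at or above a threshold. Three strategies cover the four study
conditions: ``single`` (one seed term at a time), ``union`` (terms above
threshold for *either* seed, ranked by the max similarity), and ``mean``
(similarity to the unweighted arithmetic mean of the raw seed vectors).

Query terms themselves stay on the list (a seed term trivially has
similarity 1.0 to itself) unless explicitly dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .embed import EmbeddingModel

__all__ = ["QuerySpec", "CandidateList", "cosine", "retrieve", "save_candidates", "load_candidates"]

STRATEGIES = ("single", "union", "mean")


@dataclass
class QuerySpec:
    """Seed terms plus retrieval strategy and similarity threshold."""

    query_terms: Sequence[str]
    strategy: str = "single"
    threshold: float = 0.0

    def validate(self, model: EmbeddingModel) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if not self.query_terms:
            raise ValueError("query_terms is empty")
        for t in self.query_terms:
            if t not in model.vocab:
                raise KeyError(f"query term not in vocabulary: {t!r}")
        # thresholds outside [-1, 1] are permitted: > 1 yields an empty
        # list, < -1 the whole vocabulary


@dataclass
class CandidateList:
    """(term, score) pairs in descending score, ties broken by term."""

    entries: List[Tuple[str, float]]
    threshold: float
    strategy: str

    @property
    def terms(self) -> List[str]:
        return [t for t, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u,v) / (|u||v|); raises on a zero vector."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _scores_against(model: EmbeddingModel, vec: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(vec)
    if n == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return model.unit_vectors() @ (vec / n)


def retrieve(model: EmbeddingModel, spec: QuerySpec, drop_query_terms: bool = False) -> CandidateList:
    """All vocabulary terms scoring >= spec.threshold under the strategy."""
    spec.validate(model)
    if spec.strategy == "single":
        if len(spec.query_terms) != 1:
            raise ValueError("strategy 'single' takes exactly one query term")
        scores = _scores_against(model, model.vector(spec.query_terms[0]).astype(np.float64))
    elif spec.strategy == "union":
        per_term = [
            _scores_against(model, model.vector(t).astype(np.float64)) for t in spec.query_terms
        ]
        scores = np.max(per_term, axis=0)
    else:  # mean of raw (un-normalized) query vectors
        mean_vec = np.mean(
            [model.vector(t).astype(np.float64) for t in spec.query_terms], axis=0
        )
        scores = _scores_against(model, mean_vec)

    keep = np.flatnonzero(scores >= spec.threshold)
    dropped = set(spec.query_terms) if drop_query_terms else ()
    entries = [
        (model.vocab.tokens[i], float(scores[i]))
        for i in keep
        if model.vocab.tokens[i] not in dropped
    ]
    entries.sort(key=lambda ts: (-ts[1], ts[0]))
    return CandidateList(entries, spec.threshold, spec.strategy)


def save_candidates(cands: CandidateList, path: str) -> None:
    """TSV: rank, term, score (6 dp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tterm\tscore\n")
        for rank, (term, score) in enumerate(cands.entries, 1):
            fh.write(f"{rank}\t{term}\t{score:.6f}\n")


def load_candidates(path: str, threshold: float = float("nan"), strategy: str = "") -> CandidateList:
    entries: List[Tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank\t"):
            raise ValueError(f"{path}:1: expected candidate-list header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            entries.append((parts[1], float(parts[2])))
    return CandidateList(entries, threshold, strategy)
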