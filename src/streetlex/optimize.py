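"""Threshold optimization against the expert lexicon.

The similarity threshold trades recall against precision: lower it and
the candidate list swallows the vocabulary, raise it and real slang falls
off. With an expert gold list (canonical terms plus accepted spelling
variants) in hand, we sweep the threshold over a fixed grid
(0.01..1.00, step 0.01) for each query condition and keep the threshold
maximizing F_beta with beta=2 — recall weighted twice as heavily as
precision, because a human reviewer can discard false positives far more
cheaply than they can conjure missed terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .embed import EmbeddingModel
from .retrieve import CandidateList, QuerySpec, retrieve

__all__ = [
    "ExpertLexicon",
    "ThresholdCurve",
    "load_lexicon",
    "precision_recall",
    "f_beta",
    "optimize",
    "threshold_grid",
    "save_curve",
]


@dataclass
class ExpertLexicon:
    """Gold terms with spelling-variant groups.

    ``variants`` maps each canonical term to its accepted variants (the
    canonical term itself always counts as its own variant).
    ``present_in_corpus`` flags terms attested in the training corpus;
    recall denominators use only those.
    """

    terms: List[str]
    variants: Dict[str, Set[str]] = field(default_factory=dict)
    present_in_corpus: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for canon in self.terms:
            group = self.variants.setdefault(canon, set())
            group.add(canon)
            overlap = seen & group
            if overlap:
                raise ValueError(f"variant(s) {sorted(overlap)} mapped to multiple canonical terms")
            seen |= group
        for canon in self.terms:
            self.present_in_corpus.setdefault(canon, True)

    @property
    def present_terms(self) -> List[str]:
        return [t for t in self.terms if self.present_in_corpus.get(t, True)]

    def match_of(self, entry: str) -> Optional[str]:
        """Canonical gold term this entry matches (itself or a variant)."""
        for canon, group in self.variants.items():
            if entry in group:
                return canon
        return None

    def all_variants(self) -> Set[str]:
        out: Set[str] = set()
        for group in self.variants.values():
            out |= group
        return out


def load_lexicon(path: str) -> ExpertLexicon:
    """TSV with columns term, variants (comma-separated, may be empty),
    present_in_corpus (0/1); lines starting with '#' are comments."""
    terms: List[str] = []
    variants: Dict[str, Set[str]] = {}
    present: Dict[str, bool] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term\t"):
            raise ValueError(f"{path}:1: expected lexicon header starting with 'term'")
        for lineno, line in enumerate(fh, 2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            term, var_str, pres = parts
            terms.append(term)
            variants[term] = {v for v in var_str.split(",") if v}
            present[term] = pres.strip() not in ("0", "false", "False")
    return ExpertLexicon(terms, variants, present)


def precision_recall(
    candidates: CandidateList,
    gold: ExpertLexicon,
    collapse_variants: bool = False,
    present_only: bool = True,
) -> Tuple[float, float]:
    """Precision and recall of a candidate list against the gold lexicon.

    A gold term is recalled if it or any listed variant is on the list.
    Precision judges each list entry independently by default (spelling
    variants count as separate entries, mirroring how the candidate list
    itself treats them); ``collapse_variants`` instead counts each matched
    canonical group once and shrinks the denominator accordingly.
    """
    gold_terms = gold.present_terms if present_only else gold.terms
    if not gold_terms:
        raise ValueError("gold lexicon is empty")
    listed = set(candidates.terms)
    matched = [
        canon for canon in gold_terms if gold.variants[canon] & listed
    ]
    recall = len(matched) / len(gold_terms)
    if len(candidates) == 0:
        return 0.0, recall  # precision undefined-as-zero
    if collapse_variants:
        groups: Set[str] = set()
        n_entries = 0
        for term in candidates.terms:
            canon = gold.match_of(term)
            if canon is None:
                n_entries += 1
            elif canon not in groups:
                groups.add(canon)
                n_entries += 1
        precision = len(groups) / n_entries
    else:
        hits = sum(1 for term in candidates.terms if gold.match_of(term) is not None)
        precision = hits / len(candidates)
    return precision, recall


def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F_beta = (1+beta^2) P R / (beta^2 P + R); 0 when P = R = 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def threshold_grid() -> np.ndarray:
    """The canonical sweep: 0.01 to 1.00 in steps of 0.01."""
    return np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class ThresholdCurve:
    """Precision/recall/F_beta per grid threshold for one query condition."""

    condition: str
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fbeta: np.ndarray
    beta: float

    @property
    def best_index(self) -> int:
        # ties on F_beta break toward the higher threshold (shorter list)
        best = np.flatnonzero(self.fbeta == self.fbeta.max())
        return int(best[-1])

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[self.best_index])

    def summary(self) -> Dict[str, float]:
        i = self.best_index
        return {
            "condition": self.condition,
            "threshold": float(self.thresholds[i]),
            "f_beta": float(self.fbeta[i]),
            "recall": float(self.recall[i]),
            "precision": float(self.precision[i]),
        }


def optimize(
    model: EmbeddingModel,
    queries: Sequence[str],
    gold: ExpertLexicon,
    beta: float = 2.0,
    collapse_variants: bool = False,
) -> Dict[str, ThresholdCurve]:
    """Sweep the grid under all four query conditions.

    Conditions: each of the two seed terms alone, their set union, and
    the simple mean of the two seed vectors. Retrieval is done once per
    condition at the grid floor; higher thresholds are prefix cuts of the
    same ranked list (the nesting property), so the sweep costs one
    vocabulary scan per condition.
    """
    if len(queries) != 2:
        raise ValueError("optimize expects exactly 2 query terms")
    conditions = {
        queries[0]: QuerySpec([queries[0]], "single", -1.0),
        queries[1]: QuerySpec([queries[1]], "single", -1.0),
        "union": QuerySpec(list(queries), "union", -1.0),
        "mean": QuerySpec(list(queries), "mean", -1.0),
    }
    grid = threshold_grid()
    out: Dict[str, ThresholdCurve] = {}
    for name, spec in conditions.items():
        full = retrieve(model, spec)
        P = np.zeros(len(grid))
        R = np.zeros(len(grid))
        F = np.zeros(len(grid))
        for i, tau in enumerate(grid):
            cut = CandidateList(
                [(t, s) for t, s in full.entries if s >= tau], float(tau), spec.strategy
            )
            p, r = precision_recall(cut, gold, collapse_variants=collapse_variants)
            P[i], R[i] = p, r
            F[i] = f_beta(p, r, beta)
        out[name] = ThresholdCurve(name, grid, P, R, F, beta)
    return out


def save_curve(curve: ThresholdCurve, path: str) -> None:
    """TSV: threshold, precision, recall, f_beta."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\tprecision\trecall\tf_beta\n")
        for i, tau in enumerate(curve.thresholds):
            fh.write(
                f"{tau:.2f}\t{curve.precision[i]:.6f}\t{curve.recall[i]:.6f}\t{curve.fbeta[i]:.6f}\n"
            )
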