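"""Downstream evaluation of a candidate term list.

Everything after retrieval is here: recall against the expert lexicon,
per-term drug-relevancy estimation from annotated context samples,
annotator-agreement statistics (percent agreement, Cohen's kappa, Pearson
correlation of per-term relevancy), category frequency summaries, and the
partition of marijuana-category candidates into expert-listed, technical
and genuinely novel terms.

Percentages are reported to 1 decimal place, rounded half-up, matching
the convention of the reference tables shipped under ``data/``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from random import Random
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .optimize import ExpertLexicon, load_lexicon
from .preprocess import TokenizedCorpus

__all__ = [
    "CATEGORIES",
    "RelevancyRecord",
    "NovelTermReport",
    "round_half_up",
    "recall_vs_experts",
    "drug_relevancy",
    "sample_contexts",
    "percent_agreement",
    "cohen_kappa",
    "annotator_correlation",
    "category_frequencies",
    "novel_terms",
    "data_path",
    "load_relevancy_table",
    "load_candidate_fixture",
    "load_categorization",
    "load_variant_groups",
]

CATEGORIES = ("marijuana", "process_or_paraphernalia", "other_drug", "nondrug")

CategoryAssignment = Mapping[str, str]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 84.375 -> 84.4 at 1 dp)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RelevancyRecord:
    """Annotated context sample for one term.

    ``sample_size`` is the number of documents sampled (capped at 200 by
    the sampling rule); each annotator's hits count documents in which
    the term was judged to refer to the target substance.
    """

    term: str
    sample_size: int
    annotator1_hits: int
    annotator2_hits: int

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError(f"{self.term}: sample_size must be >= 1")
        for hits in (self.annotator1_hits, self.annotator2_hits):
            if not 0 <= hits <= self.sample_size:
                raise ValueError(f"{self.term}: hits outside [0, sample_size]")


@dataclass
class NovelTermReport:
    """Partition of marijuana-category candidates."""

    expert_listed: Set[str]
    technical: Set[str]
    novel_groups: List[List[str]]  # variant-collapsed, each group sorted

    @property
    def novel_count(self) -> int:
        return len(self.novel_groups)

    @property
    def novel_terms_flat(self) -> Set[str]:
        return {t for g in self.novel_groups for t in g}


def recall_vs_experts(candidate_terms: Iterable[str], gold: ExpertLexicon) -> float:
    """Percent of corpus-present gold terms matched by the candidate list
    (spelling variants count as matches); 1 dp."""
    present = gold.present_terms
    if not present:
        raise ValueError("gold lexicon has no corpus-present terms")
    listed = set(candidate_terms)
    matched = sum(1 for canon in present if gold.variants[canon] & listed)
    return round_half_up(100.0 * matched / len(present))


def drug_relevancy(record: RelevancyRecord) -> float:
    """Mean of the two annotators' hit proportions, as a percent, 1 dp."""
    p1 = record.annotator1_hits / record.sample_size
    p2 = record.annotator2_hits / record.sample_size
    return round_half_up(100.0 * (p1 + p2) / 2.0)


def sample_contexts(
    corpus: TokenizedCorpus, term: str, n: int, seed: int
) -> List[List[str]]:
    """Uniform sample without replacement of min(n, occurrences) documents
    containing ``term``; when the term appears in fewer than n documents,
    all of them are returned. Deterministic given the seed."""
    containing = [doc for doc in corpus if term in doc]
    if not containing:
        raise KeyError(f"term not found in corpus: {term!r}")
    if n <= 0:
        return []
    if len(containing) <= n:
        return containing
    return Random(seed).sample(containing, n)


def _check_same_terms(a: CategoryAssignment, b: CategoryAssignment) -> List[str]:
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))[:5]
        raise ValueError(f"annotators labelled different term sets (e.g. {diff})")
    return sorted(a)


def percent_agreement(a: CategoryAssignment, b: CategoryAssignment) -> float:
    """100 x matching labels / terms, 1 dp."""
    terms = _check_same_terms(a, b)
    if not terms:
        raise ValueError("empty assignments")
    matches = sum(1 for t in terms if a[t] == b[t])
    return round_half_up(100.0 * matches / len(terms))


def cohen_kappa(a: CategoryAssignment, b: CategoryAssignment) -> float:
    """(p_o - p_e) / (1 - p_e), chance agreement from the two marginals."""
    terms = _check_same_terms(a, b)
    n = len(terms)
    if n == 0:
        raise ValueError("empty assignments")
    p_o = sum(1 for t in terms if a[t] == b[t]) / n
    ma = Counter(a[t] for t in terms)
    mb = Counter(b[t] for t in terms)
    p_e = sum(ma[c] * mb[c] for c in set(ma) | set(mb)) / (n * n)
    if p_e == 1.0:
        raise ZeroDivisionError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def annotator_correlation(records: Sequence[RelevancyRecord]) -> float:
    """Pearson r between the two annotators' per-term hit percentages."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation")
    x = np.array([100.0 * r.annotator1_hits / r.sample_size for r in records])
    y = np.array([100.0 * r.annotator2_hits / r.sample_size for r in records])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one annotator's percentages")
    return float(sps.pearsonr(x, y).statistic)


def category_frequencies(a: CategoryAssignment) -> Dict[str, Tuple[int, float]]:
    """Per-category (count, percent of list size), 1 dp percents."""
    counts = Counter(a.values())
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    total = sum(counts.values())
    out: Dict[str, Tuple[int, float]] = {}
    for cat in CATEGORIES:
        c = counts.get(cat, 0)
        pct = round_half_up(100.0 * c / total) if total else 0.0
        out[cat] = (c, pct)
    return out


def _collapse(terms: Set[str], groups: Mapping[str, Set[str]]) -> List[List[str]]:
    """Collapse a term set into variant groups; explicit groups win, then a
    character-repetition heuristic (gass/gasss -> gas), then singletons."""
    remaining = set(terms)
    out: List[List[str]] = []
    for canon, group in groups.items():
        members = remaining & (group | {canon})
        if members:
            out.append(sorted(members))
            remaining -= members
    squeeze: Dict[str, List[str]] = {}
    for t in sorted(remaining):
        key = _squeeze_runs(t)
        squeeze.setdefault(key, []).append(t)
    out.extend(sorted(v) for v in squeeze.values())
    return sorted(out)


def _squeeze_runs(term: str) -> str:
    out = []
    for ch in term:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def novel_terms(
    marijuana_terms: Iterable[str],
    gold: ExpertLexicon,
    known_technical: ExpertLexicon,
    variant_groups: Optional[Mapping[str, Set[str]]] = None,
) -> NovelTermReport:
    """Partition marijuana-category candidates into expert-listed (term or
    spelling variant), known-technical, and novel; novel terms are then
    collapsed into spelling-variant groups."""
    terms = set(marijuana_terms)
    expert = {t for t in terms if gold.match_of(t) is not None}
    rest = terms - expert
    technical = {t for t in rest if known_technical.match_of(t) is not None}
    novel = rest - technical
    groups = _collapse(novel, variant_groups or {})
    return NovelTermReport(expert, technical, groups)


# ---------------------------------------------------------------------------
# Packaged reference tables (candidate/marijuana lists, relevancy counts,
# lexicons). Files are TSV under streetlex/data/.
# ---------------------------------------------------------------------------


def data_path(name: str) -> str:
    return str(resources.files("streetlex").joinpath("data", name))


def load_relevancy_table(path: Optional[str] = None) -> List[Dict[str, object]]:
    """The 32-row expert-term relevancy table: term, similarity to the seed
    term, per-annotator hits/sample, candidate-list membership flag."""
    path = path or data_path("relevancy_table5.tsv")
    rows: List[Dict[str, object]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(
                {
                    "term": vals["term"],
                    "cosine": float(vals["cosine"]),
                    "record": RelevancyRecord(
                        vals["term"],
                        int(vals["sample_size"]),
                        int(vals["annotator1_hits"]),
                        int(vals["annotator2_hits"]),
                    ),
                    "on_candidate_list": vals["on_candidate_list"] == "1",
                }
            )
    return rows


def load_candidate_fixture(path: Optional[str] = None) -> List[Tuple[str, float]]:
    """The 65 marijuana-category candidate terms with their similarity to
    the seed term, in rank order."""
    path = path or data_path("candidates_table4.tsv")
    out: List[Tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, term, cos = line.rstrip("\n").split("\t")
            out.append((term, float(cos)))
    return out


def load_categorization(path: Optional[str] = None) -> Dict[str, str]:
    """term -> category map for the full 200-term candidate list."""
    path = path or data_path("synthetic_categorization.tsv")
    out: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            term, cat = line.rstrip("\n").split("\t")
            out[term] = cat
    return out


def load_variant_groups(path: Optional[str] = None) -> Dict[str, Set[str]]:
    """Explicit spelling-variant groups for novel-term collapsing."""
    path = path or data_path("novel_variants.tsv")
    out: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            canon, var_str = line.rstrip("\n").split("\t")
            out[canon] = {v for v in var_str.split(",") if v}
    return out


def load_known_technical(path: Optional[str] = None) -> ExpertLexicon:
    return load_lexicon(path or data_path("known_technical.tsv"))


def load_expert_lexicon(path: Optional[str] = None) -> ExpertLexicon:
    return load_lexicon(path or data_path("expert_lexicon.tsv"))


__all__ += ["load_known_technical", "load_expert_lexicon"]
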