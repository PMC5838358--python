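"""Synthetic tweet-corpus generator with known ground truth.

Real drug-slang discovery runs on hundreds of millions of tokens of
social-media text that cannot be redistributed. This module generates
corpora with the statistical structure the method actually exploits —
short documents, a Zipfian background vocabulary, topical context
clusters, a planted synonym set for a target "substance" topic,
polysemous terms whose target-sense share (the analog of drug relevancy)
is controlled, and planted high-association bigrams standing in for
multiword strain names — so the full pipeline can be exercised against
exact ground truth.

Each document draws a topic from a mixture; each token position then
emits, with configured probabilities, a topic slot term (the planted
"slang"), a topic context token, or a Zipfian background token. A
polysemous slot term listed under several topics acquires a realized
relevancy equal to the fraction of its emissions that came from the
target topic — realized per emission, exactly how per-document
annotation would score it. Slot terms containing a space are emitted as
two adjacent tokens, giving the phrase detector a planted bigram whose
components co-occur far above chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocess import TokenizedCorpus

__all__ = [
    "TopicSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "realized_relevancy",
    "default_config",
]


@dataclass
class TopicSpec:
    """One topical context cluster.

    ``context_vocab`` tokens are the topic's characteristic surroundings
    (disjoint from the background vocabulary by construction);
    ``slot_terms`` are the planted terms emitted in this topic's sense.
    Per token position: slot term with probability ``slot_rate``, context
    token with ``context_rate``, else a background token.
    """

    name: str
    weight: float
    context_vocab: Dict[str, float] = field(default_factory=dict)
    slot_terms: Dict[str, float] = field(default_factory=dict)
    slot_rate: float = 0.0
    context_rate: float = 0.0


@dataclass
class SyntheticConfig:
    """Corpus-level generation parameters.

    Defaults (via :func:`default_config`) emulate the study conditions at
    reduced scale: mean document length ~10.7 tokens (the tweet-corpus
    token/tweet ratio), Zipf exponent 1.1 for the background vocabulary.
    """

    n_docs: int
    doc_length: float = 10.7
    background_vocab_size: int = 5000
    zipf_exponent: float = 1.1
    topics: List[TopicSpec] = field(default_factory=list)
    target_topic: str = "target"
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs <= 0 or self.background_vocab_size <= 0:
            raise ValueError("n_docs and background_vocab_size must be positive")
        if self.doc_length <= 0:
            raise ValueError("doc_length must be positive")
        if not self.topics:
            raise ValueError("at least one topic required")
        w = sum(t.weight for t in self.topics)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"topic weights must sum to 1 (got {w})")
        names = [t.name for t in self.topics]
        if len(set(names)) != len(names):
            raise ValueError("duplicate topic names")
        if self.target_topic not in names:
            raise ValueError(f"target_topic {self.target_topic!r} not among topics")
        for t in self.topics:
            if t.slot_rate < 0 or t.context_rate < 0 or t.slot_rate + t.context_rate > 1:
                raise ValueError(f"topic {t.name}: slot_rate + context_rate must be in [0, 1]")
            if t.slot_rate > 0 and not t.slot_terms:
                raise ValueError(f"topic {t.name}: slot_rate > 0 but no slot terms")


@dataclass
class GroundTruth:
    """Exact generation trace summaries.

    ``emissions[term][topic]`` counts every emission of a planted slot
    term attributed to the emitting document's topic. ``planted_bigrams``
    lists the adjacent token pairs planted via space-containing slot
    terms. ``target_synonyms`` are the target topic's slot terms, with
    space-pairs given in merged (``a_b``) form.
    """

    target_topic: str
    target_synonyms: List[str]
    emissions: Dict[str, Dict[str, int]]
    planted_bigrams: List[Tuple[str, str]]

    def relevancy(self, term: str) -> float:
        return realized_relevancy(self, term)


def realized_relevancy(truth: GroundTruth, term: str) -> float:
    """Exact fraction of a planted term's emissions from the target topic."""
    counts = truth.emissions.get(term)
    if not counts or sum(counts.values()) == 0:
        raise KeyError(f"term not planted or never emitted: {term!r}")
    total = sum(counts.values())
    return counts.get(truth.target_topic, 0) / total


def generate(config: SyntheticConfig) -> Tuple[TokenizedCorpus, GroundTruth]:
    """Generate a tokenized corpus and its exact ground truth, fully seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    topics = config.topics
    n_topics = len(topics)

    # background Zipf distribution
    ranks = np.arange(1, config.background_vocab_size + 1, dtype=np.float64)
    p_bg = ranks ** -config.zipf_exponent
    p_bg /= p_bg.sum()
    bg_tokens = [f"bg{i:05d}" for i in range(config.background_vocab_size)]

    # per-topic normalized context / slot distributions
    ctx_tokens: List[List[str]] = []
    ctx_probs: List[np.ndarray] = []
    slot_tokens: List[List[str]] = []
    slot_probs: List[np.ndarray] = []
    for t in topics:
        toks = list(t.context_vocab)
        ps = np.array([t.context_vocab[k] for k in toks], dtype=np.float64)
        ctx_tokens.append(toks)
        ctx_probs.append(ps / ps.sum() if len(ps) else ps)
        stoks = list(t.slot_terms)
        sps = np.array([t.slot_terms[k] for k in stoks], dtype=np.float64)
        slot_tokens.append(stoks)
        slot_probs.append(sps / sps.sum() if len(sps) else sps)

    weights = np.array([t.weight for t in topics])
    doc_topics = rng.choice(n_topics, size=config.n_docs, p=weights)
    doc_lens = np.maximum(rng.poisson(config.doc_length, size=config.n_docs), 2)

    # flat position arrays so every categorical draw is one vectorized call
    total = int(doc_lens.sum())
    pos_topic = np.repeat(doc_topics, doc_lens)
    u = rng.random(total)
    slot_rates = np.array([t.slot_rate for t in topics])[pos_topic]
    ctx_rates = np.array([t.context_rate for t in topics])[pos_topic]
    is_slot = u < slot_rates
    is_ctx = ~is_slot & (u < slot_rates + ctx_rates)
    is_bg = ~is_slot & ~is_ctx

    flat = np.empty(total, dtype=object)
    n_bg = int(is_bg.sum())
    if n_bg:
        draws = rng.choice(config.background_vocab_size, size=n_bg, p=p_bg)
        flat[is_bg] = np.array(bg_tokens, dtype=object)[draws]
    emissions: Dict[str, Dict[str, int]] = {
        term: {} for t in topics for term in t.slot_terms
    }
    for ti, topic in enumerate(topics):
        mask = is_ctx & (pos_topic == ti)
        n = int(mask.sum())
        if n:
            draws = rng.choice(len(ctx_tokens[ti]), size=n, p=ctx_probs[ti])
            flat[mask] = np.array(ctx_tokens[ti], dtype=object)[draws]
        mask = is_slot & (pos_topic == ti)
        n = int(mask.sum())
        if n:
            draws = rng.choice(len(slot_tokens[ti]), size=n, p=slot_probs[ti])
            flat[mask] = np.array(slot_tokens[ti], dtype=object)[draws]
            for idx, cnt in zip(*np.unique(draws, return_counts=True)):
                by_topic = emissions[slot_tokens[ti][idx]]
                by_topic[topic.name] = by_topic.get(topic.name, 0) + int(cnt)

    corpus: TokenizedCorpus = []
    offsets = np.concatenate([[0], np.cumsum(doc_lens)])
    for d in range(config.n_docs):
        doc: List[str] = []
        for tok in flat[offsets[d] : offsets[d + 1]]:
            if " " in tok:
                doc.extend(tok.split(" "))
            else:
                doc.append(tok)
        corpus.append(doc)

    planted_bigrams = sorted(
        {
            tuple(term.split(" "))
            for t in topics
            for term in t.slot_terms
            if " " in term
        }
    )
    target = next(t for t in topics if t.name == config.target_topic)
    target_synonyms = [term.replace(" ", "_") for term in target.slot_terms]
    # ground-truth emissions are keyed by merged form for bigram terms
    emissions = {term.replace(" ", "_"): v for term, v in emissions.items()}
    return corpus, GroundTruth(config.target_topic, target_synonyms, emissions, planted_bigrams)


def save_ground_truth(truth: GroundTruth, path: str) -> None:
    """TSV: term, target_emissions, total_emissions, relevancy, is_target_synonym."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\ttarget_emissions\ttotal_emissions\trelevancy\tis_target_synonym\n")
        for term in sorted(truth.emissions):
            counts = truth.emissions[term]
            total = sum(counts.values())
            tgt = counts.get(truth.target_topic, 0)
            rel = tgt / total if total else float("nan")
            flag = 1 if term in truth.target_synonyms else 0
            fh.write(f"{term}\t{tgt}\t{total}\t{rel:.6f}\t{flag}\n")


__all__ += ["save_ground_truth"]


def default_config(
    n_docs: int = 200_000,
    seed: int = 11,
    n_synonyms: int = 10,
    context_size: int = 40,
) -> SyntheticConfig:
    """The standard study conditions at test scale (~2M tokens).

    Three topics over a shared Zipfian background:

    * ``target`` — the substance topic. ``n_synonyms`` single-token
      synonyms plus two planted bigram "strain names", all emitted only
      here (relevancy 1.0), and four polysemous terms shared with the
      distractor topics at controlled target shares (~0.75, ~0.30 above
      the separation line; ~0.08, ~0.05 below it).
    * ``distractor`` — a second topical cluster with its own synonyms,
      supplying the non-target senses of the polysemous terms.
    * ``chatter`` — pure background, the bulk of the corpus.
    """
    syns = {f"syn{i:02d}": 1.0 for i in range(n_synonyms)}
    syns["strain1a strain1b"] = 1.0
    syns["strain2a strain2b"] = 1.0
    # polysemous terms: target-topic weight w_t and distractor weight w_d
    # give expected relevancy w_t / (w_t + w_d) under equal topic weights
    # and slot rates
    poly = {"poly_hi1": (3.0, 1.0), "poly_hi2": (0.43, 1.0),
            "poly_lo1": (0.087, 1.0), "poly_lo2": (0.053, 1.0)}
    target_slots = dict(syns)
    distractor_slots = {f"dsyn{i:02d}": 1.0 for i in range(n_synonyms)}
    for term, (wt, wd) in poly.items():
        target_slots[term] = wt
        distractor_slots[term] = wd

    target = TopicSpec(
        name="target",
        weight=0.15,
        context_vocab={f"tctx{i:03d}": 1.0 for i in range(context_size)},
        slot_terms=target_slots,
        slot_rate=0.22,
        context_rate=0.45,
    )
    distractor = TopicSpec(
        name="distractor",
        weight=0.15,
        context_vocab={f"dctx{i:03d}": 1.0 for i in range(context_size)},
        slot_terms=distractor_slots,
        slot_rate=0.22,
        context_rate=0.45,
    )
    chatter = TopicSpec(name="chatter", weight=0.70)
    return SyntheticConfig(
        n_docs=n_docs,
        topics=[target, distractor, chatter],
        target_topic="target",
        seed=seed,
    )
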