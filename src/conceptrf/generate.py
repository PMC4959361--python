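"""Synthetic concept-corpus generator with planted relevant documents.

The generator emulates a concept-mapped literature collection so the whole
feedback pipeline is testable offline:

* background documents draw their concepts from a Zipf-like frequency
  distribution over the vocabulary (a handful of ubiquitous concepts, a
  long tail of rare ones), 5-200 sentences per document, 2-20 concepts per
  sentence;
* *relevant* documents additionally contain signal sentences — at a
  configurable co-occurrence rate — where a query concept appears together
  with concepts from a designated signal set, emulating documents that
  genuinely discuss the topic.  Signal sentences are padded with concepts
  from the common head of the vocabulary rather than the full Zipf tail:
  a sentence about the topic mixes topical concepts with ubiquitous ones,
  whereas rare concepts co-occurring with the query mark an *incidental*
  mention.  Ubiquitous concepts score a weighted interest near 1, so they
  do not displace the topical signal from the top of a concept profile;
* *distractor* documents mention query concepts at the same per-sentence
  rate as relevant documents but pair them with random background concepts
  instead of the signal set.  They emulate articles that match the query
  keywords without being about the topic — the situation relevance
  feedback exists to fix.  Without them a planted corpus is trivially
  solved by TF-IDF alone.

One designated relevant document gets every query concept in each of its
signal sentences, guaranteeing a top-tier initial A-TF-IDF score so a
simulated user always has at least one relevant document to select.  All
randomness flows from the single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConceptDocument, Corpus, Query
from .evaluation import Grade, RelevanceJudgments

__all__ = ["GeneratorSpec", "generate_corpus", "judgments_for"]


@dataclass
class GeneratorSpec:
    """Parameters of a planted synthetic corpus.

    ``co_occurrence_rate`` is the probability that a sentence of a relevant
    document is a signal sentence (query concept + signal concepts); the
    same rate governs how often distractor sentences mention a query
    concept, so relevant and distractor documents are indistinguishable by
    query-term frequency alone.
    """

    n_docs: int = 100
    n_relevant: int = 8
    n_distractors: int = 15
    vocab_size: int = 2000
    sentences_per_doc: tuple = (5, 200)
    tokens_per_sentence: tuple = (2, 20)
    query_size: int = 3
    signal_concepts: list | None = None  # auto-chosen when None
    n_signal: int = 6
    co_occurrence_rate: float = 0.6
    zipf_exponent: float = 1.1
    common_head: int = 20  # signal-sentence padding comes from these top ranks
    seed: int = 0

    def validate(self) -> None:
        if self.n_relevant > self.n_docs:
            raise ValueError("n_relevant cannot exceed n_docs")
        if self.n_relevant + self.n_distractors > self.n_docs:
            raise ValueError("n_relevant + n_distractors cannot exceed n_docs")
        if self.query_size < 1 or self.query_size > self.vocab_size:
            raise ValueError("query_size must be in [1, vocab_size]")
        if not (0.0 <= self.co_occurrence_rate <= 1.0):
            raise ValueError("co_occurrence_rate must be in [0, 1]")
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ValueError("invalid sentences_per_doc range")
        lo, hi = self.tokens_per_sentence
        if lo < 1 or hi < lo:
            raise ValueError("invalid tokens_per_sentence range")
        if self.vocab_size < self.query_size + self.n_signal:
            raise ValueError("vocabulary too small for query plus signal concepts")


def _token(i: int) -> str:
    return f"C{i + 1:07d}"


def generate_corpus(spec: GeneratorSpec):
    """Generate ``(corpus, query, relevant_doc_ids)`` deterministically.

    Vocabulary ranks follow probabilities proportional to 1/rank^s.  Query
    and signal concepts are drawn (disjointly) from the mid-frequency band
    of ranks 20-200: frequent enough to occur, rare enough to discriminate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = 1.0 / ranks ** spec.zipf_exponent
    probs /= probs.sum()
    head = min(spec.common_head, spec.vocab_size)
    head_probs = probs[:head] / probs[:head].sum()

    band_lo, band_hi = 20, min(200, spec.vocab_size)
    band = np.arange(band_lo - 1, band_hi)
    picked = rng.choice(band, size=spec.query_size + spec.n_signal, replace=False)
    query_ids = picked[: spec.query_size]
    if spec.signal_concepts is None:
        signal = [_token(i) for i in picked[spec.query_size:]]
    else:
        signal = list(spec.signal_concepts)
    query = Query([_token(i) for i in query_ids])
    query_tokens = sorted(query.concepts)

    width = max(4, len(str(spec.n_docs)))
    doc_ids = [f"d{i + 1:0{width}d}" for i in range(spec.n_docs)]
    roles = ["background"] * spec.n_docs
    special = rng.choice(spec.n_docs, size=spec.n_relevant + spec.n_distractors,
                         replace=False)
    relevant_idx = special[: spec.n_relevant]
    for i in relevant_idx:
        roles[i] = "relevant"
    for i in special[spec.n_relevant:]:
        roles[i] = "distractor"
    anchor = int(relevant_idx[0]) if spec.n_relevant else -1

    s_lo, s_hi = spec.sentences_per_doc
    t_lo, t_hi = spec.tokens_per_sentence

    documents = []
    for i, doc_id in enumerate(doc_ids):
        n_sent = int(rng.integers(s_lo, s_hi + 1))
        lengths = rng.integers(t_lo, t_hi + 1, size=n_sent)
        pool = rng.choice(spec.vocab_size, size=int(lengths.sum()), p=probs)
        sentences = []
        pos = 0
        for length in lengths:
            sent = [_token(j) for j in pool[pos:pos + length]]
            pos += int(length)
            role = roles[i]
            if role != "background" and rng.random() < spec.co_occurrence_rate:
                if i == anchor:
                    planted = list(query_tokens)
                else:
                    n_q = int(rng.integers(1, len(query_tokens) + 1))
                    planted = list(rng.choice(query_tokens, size=n_q, replace=False))
                if role == "relevant":
                    n_s = int(rng.integers(1, min(3, len(signal)) + 1))
                    planted += list(rng.choice(signal, size=n_s, replace=False))
                    # topical sentences pad with ubiquitous concepts, not
                    # with the rare tail: an incidental rare co-occurrence
                    # would mimic topical signal under an interest measure
                    pad = max(0, len(sent) - len(planted))
                    fill = rng.choice(head, size=pad, p=head_probs)
                    sent = planted + [_token(j) for j in fill]
                else:
                    # distractor: query mention amid arbitrary content
                    sent = planted + sent[len(planted):]
                if len(sent) > len(planted):
                    perm = rng.permutation(len(sent))
                    sent = [sent[j] for j in perm]
            elif i == anchor and rng.random() < 0.5:
                # the anchor document stays retrievable by plain TF-IDF even
                # when the co-occurrence rate is 0 (negative control)
                sent = [str(rng.choice(query_tokens))] + sent[1:]
            sentences.append(sent)
        documents.append(ConceptDocument(doc_id, sentences))

    relevant_ids = {doc_ids[i] for i in relevant_idx}
    return Corpus(documents), query, relevant_ids


def judgments_for(relevant_ids, topic_id: str = "T1") -> RelevanceJudgments:
    """Qrels for a planted corpus: every planted document DEFINITELY relevant."""
    judgments = RelevanceJudgments()
    for doc_id in sorted(relevant_ids):
        judgments.set(topic_id, doc_id, Grade.DEFINITELY)
    return judgments
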