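"""Initial document ranking by accumulative TF-IDF.

A query is a small set of concepts; each document is scored by summing the
TF-IDF weights of the query's concepts in that document (accumulative
TF-IDF, A-TF-IDF):

    TF(c, d)   = f_c^d / sum_j f_{c_j}^d          (token multiplicity)
    IDF(c, D)  = log10(|D| / DF_c)
    A-TF-IDF   = sum_{c in Q} TF(c, d) * IDF(c, D)

Documents are ranked by descending score; ties break on ascending doc_id so
rankings are deterministic.  Log base 10 is used throughout — the ranking
is invariant to the base, which only fixes the reported score values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .model import ConceptDocument, Corpus, Query

__all__ = [
    "ScoredDocument",
    "RankedList",
    "term_frequency",
    "inverse_document_frequency",
    "tf_idf",
    "a_tf_idf",
    "rank_initial",
]


@dataclass(frozen=True)
class ScoredDocument:
    """A document identifier with its retrieval score (A-TF-IDF or RBO)."""

    doc_id: str
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError(f"score must be finite and >= 0, got {self.score}")


@dataclass
class RankedList:
    """An ordered list of scored documents (best first)."""

    entries: list

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ScoredDocument]:
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def doc_ids(self) -> list:
        return [e.doc_id for e in self.entries]

    def top(self, n: int) -> list:
        """The identifiers of the first *n* documents."""
        return [e.doc_id for e in self.entries[:n]]

    def score_of(self, doc_id: str) -> float:
        for e in self.entries:
            if e.doc_id == doc_id:
                return e.score
        raise KeyError(doc_id)


def term_frequency(concept: str, doc: ConceptDocument) -> float:
    """Frequency of *concept* in *doc* over the document's total token count.

    Multiplicity is counted over the flattened tokens of all sentences.
    Raises for a document with no concepts (the ratio is undefined there).
    """
    total = doc.token_count
    if total == 0:
        raise ValueError(f"document {doc.doc_id!r} has no concepts")
    count = sum(1 for tok in doc.tokens() if tok == concept)
    return count / total


def inverse_document_frequency(concept: str, corpus: Corpus) -> float:
    """log10(|D| / DF_c); 0 for a concept absent from the corpus.

    A concept contained in every document scores 0 (log 1); a concept that
    appears nowhere cannot discriminate documents, so its IDF is defined
    as 0 rather than left undefined.
    """
    df = corpus.document_frequency(concept)
    if df == 0:
        return 0.0
    return math.log10(len(corpus) / df)


def tf_idf(concept: str, doc: ConceptDocument, corpus: Corpus) -> float:
    """TF-IDF weight of one concept in one document; 0 for an empty document."""
    if doc.token_count == 0:
        return 0.0
    return term_frequency(concept, doc) * inverse_document_frequency(concept, corpus)


def a_tf_idf(query: Query, doc: ConceptDocument, corpus: Corpus) -> float:
    """Accumulative TF-IDF of *doc* for *query*: sum of per-concept weights."""
    total = doc.token_count
    if total == 0:
        return 0.0
    # one pass over the tokens instead of |Q| scans
    counts: dict = {c: 0 for c in query.concepts}
    for tok in doc.tokens():
        if tok in counts:
            counts[tok] += 1
    score = 0.0
    for concept, count in counts.items():
        if count:
            score += (count / total) * inverse_document_frequency(concept, corpus)
    return score


def rank_initial(query: Query, corpus: Corpus) -> RankedList:
    """Rank every corpus document by descending A-TF-IDF.

    Ties (including the all-zero case) break on ascending doc_id.
    """
    scored = [ScoredDocument(doc.doc_id, a_tf_idf(query, doc, corpus)) for doc in corpus]
    scored.sort(key=lambda e: (-e.score, e.doc_id))
    return RankedList(scored)
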