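"""Weighted-interest association mining of relevance feedback.

The user-selected documents Z are split into sentences, each treated as a
transaction.  For every unique concept c in Z the rule Q -> {c} is scored
with a *weighted interest* measure — the classic interest/lift extended
with fractional query counts so that a sentence containing only part of a
multi-concept query still contributes:

    CNT(Q)_s      = |{c : c in Q and c in s}| / |Q|        (partial count)
    CNT(c)_s      = 1 if c in s else 0                     (binary count)
    CNT(Q u c)_s  = CNT(Q)_s * CNT(c)_s
    f_Q^w         = sum_s CNT(Q)_s
    f_c           = sum_s CNT(c)_s
    f_{Qc}^w      = sum_s CNT(Q u c)_s
    I_c^w         = N * f_{Qc}^w / (f_Q^w * f_c),   N = number of transactions

All membership is set-based: within-sentence multiplicity is ignored for
both the query concepts and the candidate concept.  N is the sentence count
of the transaction set being mined (the pooled feedback for Z, a document's
own sentence count when profiling that document).  I^w > 1 indicates a
positive association under the independence baseline.

The top-k concepts by I^w form a *k-profile*, the compact representation of
the user's intention that later rounds match against each document's own
k-profile.  Ties break on higher weighted joint frequency, then ascending
concept token, so profiles are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

from .model import ConceptDocument, Query, Sentence

__all__ = [
    "FeedbackSet",
    "AssociationScore",
    "KProfile",
    "partial_count_query",
    "binary_count_concept",
    "joint_partial_count",
    "weighted_frequency_query",
    "frequency_concept",
    "weighted_joint_frequency",
    "weighted_interest",
    "mine_associations",
    "build_k_profile",
]


@dataclass
class FeedbackSet:
    """The pooled transaction set Z mined against the query.

    Sentences are pooled in document order then sentence order; the
    transaction count N is the number of pooled sentences (empty sentences
    included — they are transactions with zero counts).
    """

    source_doc_ids: list
    sentences: list

    @classmethod
    def from_documents(cls, documents) -> "FeedbackSet":
        docs = list(documents)
        sentences: list = []
        for doc in docs:
            sentences.extend(doc.sentences)
        return cls([d.doc_id for d in docs], sentences)

    @property
    def transaction_count(self) -> int:
        return len(self.sentences)

    def unique_concepts(self) -> set:
        out: set = set()
        for sent in self.sentences:
            out.update(sent)
        return out


@dataclass(frozen=True)
class AssociationScore:
    """The rule Q -> {concept} with its weighted interest and frequencies."""

    concept: str
    weighted_interest: float
    f_q_weighted: float
    f_c: int
    f_joint_weighted: float


@dataclass
class KProfile:
    """Top-k concepts ranked by weighted interest against a query.

    ``concepts`` is an ordered list of ``(token, I^w)`` pairs, descending
    I^w under the deterministic tie-break; it holds at most k entries and
    no duplicates.
    """

    query: Query
    k: int
    concepts: list

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def tokens(self) -> list:
        """The ranked concept tokens only."""
        return [c for c, _ in self.concepts]

    def to_json(self) -> str:
        return json.dumps(
            {
                "query": sorted(self.query.concepts),
                "k": self.k,
                "concepts": [{"concept": c, "iw": iw} for c, iw in self.concepts],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KProfile":
        obj = json.loads(text)
        return cls(
            Query(obj["query"]),
            int(obj["k"]),
            [(entry["concept"], float(entry["iw"])) for entry in obj["concepts"]],
        )


# ---------------------------------------------------------------------------
# per-sentence counts
# ---------------------------------------------------------------------------


def partial_count_query(query: Query, sentence: Sentence) -> float:
    """Fraction of the query's concepts present in the sentence, in [0, 1]."""
    sent = set(sentence)
    return sum(1 for c in query.concepts if c in sent) / len(query)


def binary_count_concept(concept: str, sentence: Sentence) -> int:
    """1 if the sentence contains the concept, else 0."""
    return 1 if concept in sentence else 0


def joint_partial_count(query: Query, concept: str, sentence: Sentence) -> float:
    """Partial count of Q and the concept jointly: the product of the two counts."""
    return partial_count_query(query, sentence) * binary_count_concept(concept, sentence)


# ---------------------------------------------------------------------------
# frequencies over a feedback set
# ---------------------------------------------------------------------------


def weighted_frequency_query(query: Query, z: FeedbackSet) -> float:
    """f_Q^w: sum of the query's partial counts over all sentences of Z."""
    return sum(partial_count_query(query, s) for s in z.sentences)


def frequency_concept(concept: str, z: FeedbackSet) -> int:
    """f_c: number of sentences of Z containing the concept."""
    return sum(binary_count_concept(concept, s) for s in z.sentences)


def weighted_joint_frequency(query: Query, concept: str, z: FeedbackSet) -> float:
    """f_{Qc}^w: sum of the joint partial counts over all sentences of Z."""
    return sum(joint_partial_count(query, concept, s) for s in z.sentences)


def weighted_interest(query: Query, concept: str, z: FeedbackSet) -> float:
    """Weighted interest I^w of the rule Q -> {concept} over Z.

    The concept must occur somewhere in Z.  When the query is entirely
    absent from Z (f_Q^w = 0) there is no evidence of association and the
    measure is defined as 0 rather than dividing by zero.
    """
    f_c = frequency_concept(concept, z)
    if f_c == 0:
        raise ValueError(f"concept {concept!r} not in feedback")
    f_q = weighted_frequency_query(query, z)
    if f_q == 0:
        return 0.0
    f_joint = weighted_joint_frequency(query, concept, z)
    return z.transaction_count * f_joint / (f_q * f_c)


def mine_associations(query: Query, z: FeedbackSet) -> list:
    """Score the rule Q -> {c} for every unique concept c of Z.

    Returns one :class:`AssociationScore` per unique concept, sorted by
    descending I^w with ties broken on higher f_{Qc}^w then ascending
    concept token.  Implemented sentence-major (one pass over Z) so mining
    costs O(total unique concept occurrences), not O(|concepts| * |Z|).
    """
    n = z.transaction_count
    if n == 0:
        raise ValueError("empty feedback set")
    qset = query.concepts
    qlen = len(qset)
    f_q = 0.0
    f_c: dict = {}
    f_joint: dict = {}
    for sentence in z.sentences:
        sent = set(sentence)
        cnt_q = len(qset & sent) / qlen
        f_q += cnt_q
        for c in sent:
            f_c[c] = f_c.get(c, 0) + 1
            f_joint[c] = f_joint.get(c, 0.0) + cnt_q
    scores = []
    for c, fc in f_c.items():
        fj = f_joint[c] if f_c[c] else 0.0
        iw = 0.0 if f_q == 0 else n * fj / (f_q * fc)
        scores.append(AssociationScore(c, iw, f_q, fc, fj))
    scores.sort(key=lambda a: (-a.weighted_interest, -a.f_joint_weighted, a.concept))
    return scores


def build_k_profile(
    query: Query,
    source: Union[FeedbackSet, ConceptDocument],
    k: int,
) -> KProfile:
    """Top-k concepts of a feedback set or of a single document.

    When profiling a document, its own sentences are the transaction set
    and N is its own sentence count.  If the source holds fewer than k
    unique concepts the profile is simply shorter; an empty source yields
    an empty profile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(source, ConceptDocument):
        source = FeedbackSet.from_documents([source])
    if source.transaction_count == 0:
        return KProfile(query, k, [])
    scores = mine_associations(query, source)
    return KProfile(query, k, [(a.concept, a.weighted_interest) for a in scores[:k]])
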