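"""Truncated rank-biased overlap between k-profiles, and RBO re-ranking.

Rank-biased overlap (RBO) compares two ranked lists with geometrically
decaying emphasis on depth:

    RBO(a, b) = (1 - phi) * sum_{d=1..k} phi^(d-1) * |a[:d] ∩ b[:d]| / d

phi in (0, 1) controls the decay (smaller = more top-weighted; 0.9 is the
conventional choice).  The truncated form evaluated here sums exactly the
first k depths with outer factor (1 - phi) — no extrapolated tail — so two
identical length-k lists score 1 - phi^k, not 1.  Lists shorter than the
current depth contribute their whole prefix (incomplete-ranking handling).

For re-ranking, every corpus document's own k-profile is compared against
the feedback k-profile and documents are ordered by descending RBO.
"""

from __future__ import annotations

from dataclasses import dataclass

from .associations import FeedbackSet, KProfile, build_k_profile, mine_associations
from .model import Corpus, Query
from .ranking import RankedList, ScoredDocument

__all__ = [
    "RboParameters",
    "rbo_similarity",
    "rbo_agreement_terms",
    "profile_corpus",
    "rank_by_profile",
]


@dataclass(frozen=True)
class RboParameters:
    """RBO decay phi in (0, 1) and profile depth k >= 1."""

    phi: float = 0.9
    k: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie strictly between 0 and 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _check_lists(a, b, params: RboParameters) -> None:
    for name, lst in (("first", a), ("second", b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"{name} list contains duplicate concepts")
        if len(lst) > params.k:
            raise ValueError(f"{name} list longer than profile depth k={params.k}")


def rbo_agreement_terms(a, b, params: RboParameters) -> list:
    """Per-depth (overlap, agreement, weighted term) decomposition of RBO.

    The weighted term at depth d is phi^(d-1) * agreement; the terms summed
    and multiplied by (1 - phi) give :func:`rbo_similarity` exactly.  Full
    precision is kept internally; round only when reporting.
    """
    _check_lists(a, b, params)
    terms = []
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    for depth in range(1, params.k + 1):
        if depth <= len(a):
            x = a[depth - 1]
            if x in seen_b:
                overlap += 1
            seen_a.add(x)
        if depth <= len(b):
            y = b[depth - 1]
            if y in seen_a:
                overlap += 1
            seen_b.add(y)
        agreement = overlap / depth
        terms.append((overlap, agreement, params.phi ** (depth - 1) * agreement))
    return terms


def rbo_similarity(a, b, params: RboParameters) -> float:
    """Truncated RBO between two ranked concept lists, in [0, 1 - phi^k]."""
    _check_lists(a, b, params)
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    total = 0.0
    weight = 1.0  # phi^(depth-1)
    for depth in range(1, params.k + 1):
        if depth <= len(a):
            x = a[depth - 1]
            if x in seen_b:
                overlap += 1
            seen_a.add(x)
        if depth <= len(b):
            y = b[depth - 1]
            if y in seen_a:
                overlap += 1
            seen_b.add(y)
        total += weight * overlap / depth
        weight *= params.phi
    return (1.0 - params.phi) * total


def profile_corpus(corpus: Corpus, query: Query) -> dict:
    """Full ranked concept list (all depths) for every document, by doc_id.

    Document profiles depend on the query but not on the feedback, so they
    can be mined once and truncated to any k — useful as a cache when the
    same corpus is re-ranked at several profile depths or across rounds.
    """
    profiles: dict = {}
    for doc in corpus:
        z = FeedbackSet.from_documents([doc])
        if z.transaction_count == 0:
            profiles[doc.doc_id] = []
        else:
            profiles[doc.doc_id] = [a.concept for a in mine_associations(query, z)]
    return profiles


def rank_by_profile(
    feedback_profile: KProfile,
    corpus: Corpus,
    query: Query,
    params: RboParameters,
    doc_profiles: dict | None = None,
) -> RankedList:
    """Re-rank the whole corpus by RBO against the feedback k-profile.

    Each document's own k-profile (same query, same k) is compared with
    ``feedback_profile``; documents are ordered by descending RBO with the
    same tie-break as the initial ranking (ascending doc_id).
    ``doc_profiles`` may carry pre-mined full concept lists from
    :func:`profile_corpus`; they are truncated to k here.
    """
    if len(feedback_profile) == 0:
        raise ValueError("no feedback profile")
    fb = feedback_profile.tokens[: params.k]
    scored = []
    for doc in corpus:
        if doc_profiles is not None:
            prof = doc_profiles[doc.doc_id][: params.k]
        else:
            prof = build_k_profile(query, doc, params.k).tokens
        scored.append(ScoredDocument(doc.doc_id, rbo_similarity(fb, prof, params)))
    scored.sort(key=lambda e: (-e.score, e.doc_id))
    return RankedList(scored)
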