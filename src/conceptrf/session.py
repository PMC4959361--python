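"""Multi-round search sessions and retention of user-selected documents.

A session holds a query, a corpus, the top-list size chi the user reviews,
and the per-round history of rankings and selections.  Round 0 is the
initial A-TF-IDF ranking; each feedback submission pools the selected
documents into a transaction set Z, builds the feedback k-profile, re-ranks
the corpus by RBO, and then adjusts the new top-chi window so that every
document the user already marked relevant stays visible:

Let r be the selected documents and chi' the next round's top list.  The
selected documents missing from chi' (xi = r \\ chi') replace the lowest-
ranked documents of chi' that are not themselves in r, walking both xi and
chi' from the end.  Higher-ranked newcomers are preserved because they are
the most likely new relevant documents.

Each round's Z is that round's selection only; past selections are kept in
the history for audit.  Sessions are reproducible: the same corpus, query,
selections and parameters give identical lists every round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .associations import FeedbackSet, build_k_profile
from .model import Corpus, Query, read_corpus
from .ranking import RankedList, ScoredDocument, rank_initial
from .rbo import RboParameters, profile_corpus, rank_by_profile

__all__ = [
    "RoundRecord",
    "SessionState",
    "retain_feedback",
    "run_initial",
    "submit_feedback",
    "save_session",
    "load_session",
]

logger = logging.getLogger(__name__)


@dataclass
class RoundRecord:
    """One round's ranking and the documents the user selected from it."""

    ranking: RankedList
    selected: list = field(default_factory=list)


@dataclass
class SessionState:
    """State of a multi-round feedback search over one corpus and query."""

    query: Query
    corpus: Corpus
    chi: int = 10
    params: RboParameters = field(default_factory=RboParameters)
    round: int = 0
    history: list = field(default_factory=list)
    corpus_path: str | None = None  # provenance for persisted sessions
    _doc_profiles: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.chi < 1:
            raise ValueError("chi must be >= 1")

    def current_ranking(self) -> RankedList:
        if not self.history:
            raise ValueError("no search has been run yet")
        return self.history[-1].ranking

    def current_top(self) -> list:
        return self.current_ranking().top(self.chi)


def retain_feedback(prev_top, selected, next_top) -> list:
    """Keep every selected document inside the next round's top list.

    ``prev_top`` is the previous top-chi, ``selected`` (r) the user's
    selections from it, ``next_top`` (chi') the new top-chi of equal
    length.  The selected documents absent from chi' replace, from the
    bottom up, the lowest-ranked chi' entries not in r; documents already
    in r are never displaced.  Order within the replacements mirrors the
    tail of the selection list.
    """
    prev_set = set(prev_top)
    for d in selected:
        if d not in prev_set:
            raise ValueError(f"selected document {d!r} was not in the reviewed top list")
    if len(next_top) != len(prev_top):
        raise ValueError("next_top and prev_top must have the same length")
    r = set(selected)
    next_set = set(next_top)
    xi = [d for d in selected if d not in next_set]
    if not xi:
        return list(next_top)
    replaceable = sum(1 for d in next_top if d not in r)
    if len(xi) > replaceable:
        raise ValueError("cannot retain all feedback")
    out = list(next_top)
    j = len(xi) - 1  # consume xi from its end
    for i in range(len(out) - 1, -1, -1):
        if j < 0:
            break
        if out[i] in r:
            continue
        out[i] = xi[j]
        j -= 1
    return out


def run_initial(state: SessionState) -> RankedList:
    """Round-0 search: rank the whole corpus by A-TF-IDF and record it."""
    if state.round != 0 or state.history:
        raise ValueError("initial search must be the first action of a session")
    ranking = rank_initial(state.query, state.corpus)
    state.history.append(RoundRecord(ranking))
    logger.info(
        "round 0: initial ranking, top-%d = %s", state.chi, ranking.top(state.chi)
    )
    return ranking


def submit_feedback(state: SessionState, selected) -> RankedList:
    """Run one feedback round from the user's selections.

    Duplicated selections collapse; every selection must lie in the current
    top-chi.  The selected documents are pooled into Z, the feedback
    k-profile is mined, the corpus is re-ranked by RBO, and the retention
    rule is applied to the top-chi window.  Returns the adjusted ranking
    (the adjusted top-chi followed by the remaining documents in RBO
    order) and appends it to the history.
    """
    deduped: list = []
    for d in selected:
        if d not in deduped:
            deduped.append(d)
    if not deduped:
        raise ValueError("no feedback provided")
    top = state.current_top()
    top_set = set(top)
    for d in deduped:
        if d not in top_set:
            raise ValueError(f"selected document {d!r} is not in the current top-{state.chi}")

    z = FeedbackSet.from_documents([state.corpus[d] for d in deduped])
    profile = build_k_profile(state.query, z, state.params.k)
    if state._doc_profiles is None:
        state._doc_profiles = profile_corpus(state.corpus, state.query)
    ranked = rank_by_profile(
        profile, state.corpus, state.query, state.params, doc_profiles=state._doc_profiles
    )
    adjusted_top = retain_feedback(top, deduped, ranked.top(state.chi))

    by_id = {e.doc_id: e for e in ranked}
    entries = [by_id[d] for d in adjusted_top]
    placed = set(adjusted_top)
    entries.extend(e for e in ranked if e.doc_id not in placed)
    adjusted = RankedList(entries)

    state.history[-1].selected = deduped
    state.history.append(RoundRecord(adjusted))
    state.round += 1
    logger.info(
        "round %d: feedback %s, top-%d = %s",
        state.round, deduped, state.chi, adjusted.top(state.chi),
    )
    return adjusted


# ---------------------------------------------------------------------------
# persistence (used by the CLI between invocations)
# ---------------------------------------------------------------------------


def save_session(state: SessionState, path) -> None:
    """Persist a session as JSON; the corpus is stored by path, not inline."""
    if state.corpus_path is None:
        raise ValueError("cannot persist a session without a corpus_path")
    payload = {
        "corpus_path": state.corpus_path,
        "query": sorted(state.query.concepts),
        "chi": state.chi,
        "phi": state.params.phi,
        "k": state.params.k,
        "round": state.round,
        "history": [
            {
                "ranking": [[e.doc_id, e.score] for e in rec.ranking],
                "selected": rec.selected,
            }
            for rec in state.history
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_session(path) -> SessionState:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    corpus = read_corpus(obj["corpus_path"])
    state = SessionState(
        query=Query(obj["query"]),
        corpus=corpus,
        chi=int(obj["chi"]),
        params=RboParameters(phi=float(obj["phi"]), k=int(obj["k"])),
        round=int(obj["round"]),
        corpus_path=obj["corpus_path"],
    )
    for rec in obj["history"]:
        ranking = RankedList([ScoredDocument(d, s) for d, s in rec["ranking"]])
        state.history.append(RoundRecord(ranking, list(rec["selected"])))
    return state
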