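"""Retrieval evaluation: graded judgments, AP/MAP, and a simulated user.

Judgments follow the TREC qrels dialect (``topic_id 0 doc_id grade``) with
three grades: 0 = NOT, 1 = POSSIBLY, 2 = DEFINITELY relevant.  Binary
relevance is derived under two gold standards: ``possibly+`` (POSSIBLY or
DEFINITELY counts as relevant) and ``definitely-only``.

Average precision at a cutoff N is computed over the top-N list only: the
mean of precision@rank at each rank <= N holding a relevant document, with
the denominator being the number of relevant documents retrieved within N
(0 when none is found).  This pairs MAP@N with counts of relevant documents
in the top N; it is a convention of this package, stated explicitly because
cutoff MAP denominators vary across the literature.

The simulated user models the standard explicit-feedback protocol: at each
round they review the top chi documents, select every judged-relevant one,
and submit the selection.  A topic whose current top-chi holds no relevant
document cannot produce feedback and is marked non-feedback-capable; such
topics are excluded from later-round MAP.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .ranking import RankedList
from .session import SessionState, run_initial, submit_feedback

__all__ = [
    "Grade",
    "RelevanceJudgments",
    "read_judgments",
    "write_judgments",
    "average_precision",
    "mean_average_precision",
    "RoundMetrics",
    "SimulationResult",
    "simulate_user",
    "write_metrics_csv",
]


class Grade(Enum):
    """Graded relevance of a document to a topic."""

    NOT = 0
    POSSIBLY = 1
    DEFINITELY = 2


@dataclass
class RelevanceJudgments:
    """topic_id -> doc_id -> grade; unjudged documents count as NOT."""

    grades: dict = field(default_factory=dict)

    def grade(self, topic_id: str, doc_id: str) -> Grade:
        return self.grades.get(topic_id, {}).get(doc_id, Grade.NOT)

    def set(self, topic_id: str, doc_id: str, grade: Grade) -> None:
        self.grades.setdefault(topic_id, {})[doc_id] = grade

    def topics(self) -> list:
        return sorted(self.grades)

    def relevant_docs(self, topic_id: str, mode: str = "possibly+") -> set:
        """Binary relevant set under a gold standard.

        ``possibly+`` treats POSSIBLY and DEFINITELY as relevant;
        ``definitely-only`` restricts to DEFINITELY.
        """
        if mode == "possibly+":
            keep = {Grade.POSSIBLY, Grade.DEFINITELY}
        elif mode == "definitely-only":
            keep = {Grade.DEFINITELY}
        else:
            raise ValueError(f"unknown relevance mode: {mode!r}")
        return {d for d, g in self.grades.get(topic_id, {}).items() if g in keep}


def read_judgments(path) -> RelevanceJudgments:
    """Read whitespace-separated qrels: ``topic_id 0 doc_id grade``."""
    judgments = RelevanceJudgments()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        topic_id, _, doc_id, grade_tok = parts
        try:
            grade = Grade(int(grade_tok))
        except ValueError:
            raise ValueError(f"line {lineno}: unknown grade token {grade_tok!r}")
        judgments.set(topic_id, doc_id, grade)
    return judgments


def write_judgments(judgments: RelevanceJudgments, path) -> None:
    lines = []
    for topic_id in judgments.topics():
        for doc_id in sorted(judgments.grades[topic_id]):
            lines.append(f"{topic_id} 0 {doc_id} {judgments.grades[topic_id][doc_id].value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def average_precision(ranked, relevant: set, cutoff: int) -> float:
    """AP over the top-*cutoff* ranks; 0 if no relevant document appears.

    ``ranked`` may be a :class:`RankedList` or any ordered iterable of
    doc_ids.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    doc_ids = ranked.doc_ids if isinstance(ranked, RankedList) else list(ranked)
    if not doc_ids:
        raise ValueError("empty ranking")
    hits = 0
    precisions = []
    for rank, doc_id in enumerate(doc_ids[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            precisions.append(hits / rank)
    if not precisions:
        return 0.0
    return sum(precisions) / len(precisions)


def mean_average_precision(runs, cutoff: int) -> float:
    """Mean of per-topic AP over (ranking, relevant-set) pairs."""
    runs = list(runs)
    if not runs:
        raise ValueError("mean_average_precision needs at least one run")
    return sum(average_precision(r, rel, cutoff) for r, rel in runs) / len(runs)


@dataclass
class RoundMetrics:
    """Per-round bookkeeping for one simulated topic."""

    round: int
    ranking: RankedList
    selected: list
    rel_in_top10: int
    rel_in_top20: int
    ap10: float
    ap20: float


@dataclass
class SimulationResult:
    topic_id: str
    rounds: list
    feedback_capable: bool

    def map_at(self, cutoff: int, round_index: int) -> float:
        rec = self.rounds[round_index]
        return rec.ap10 if cutoff == 10 else rec.ap20


def simulate_user(
    state: SessionState,
    relevant: set,
    rounds: int = 2,
    topic_id: str = "topic",
) -> SimulationResult:
    """Run a session with a user who selects every relevant top-chi document.

    ``rounds`` counts search rounds including the initial one (rounds=2 is
    initial + one feedback round).  If at some round no relevant document
    sits in the top chi, the user cannot give feedback: the simulation
    stops there and the topic is flagged non-feedback-capable.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")

    def metrics(ranking: RankedList, rnd: int, selected) -> RoundMetrics:
        return RoundMetrics(
            round=rnd,
            ranking=ranking,
            selected=list(selected),
            rel_in_top10=sum(1 for d in ranking.top(10) if d in relevant),
            rel_in_top20=sum(1 for d in ranking.top(20) if d in relevant),
            ap10=average_precision(ranking, relevant, 10),
            ap20=average_precision(ranking, relevant, 20),
        )

    ranking = run_initial(state)
    capable = True
    records = []
    for rnd in range(1, rounds):
        selection = [d for d in ranking.top(state.chi) if d in relevant]
        if not selection:
            capable = False
            break
        records.append(metrics(ranking, rnd - 1, selection))
        ranking = submit_feedback(state, selection)
    records.append(metrics(ranking, len(records), []))
    return SimulationResult(topic_id, records, capable)


def write_metrics_csv(results, path, cutoff_pairs=(10, 20)) -> None:
    """Write per-topic, per-round metrics plus a MAP summary row per round."""
    results = list(results)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic_id", "round", "rel_in_top10", "rel_in_top20", "ap10", "ap20"])
        max_rounds = max((len(r.rounds) for r in results), default=0)
        for res in results:
            for rec in res.rounds:
                writer.writerow(
                    [res.topic_id, rec.round, rec.rel_in_top10, rec.rel_in_top20,
                     f"{rec.ap10:.4f}", f"{rec.ap20:.4f}"]
                )
        for rnd in range(max_rounds):
            rows = [r.rounds[rnd] for r in results if len(r.rounds) > rnd]
            if rows:
                writer.writerow(
                    ["MAP", rnd, "", "",
                     f"{sum(r.ap10 for r in rows) / len(rows):.4f}",
                     f"{sum(r.ap20 for r in rows) / len(rows):.4f}"]
                )
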