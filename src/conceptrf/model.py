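"""Domain types and I/O for concept-annotated document corpora.

A *concept document* is an article that has already been mapped to standard
biomedical concept identifiers (UMLS CUIs or any opaque tokens): an ordered
list of sentences, each sentence an ordered list of concept tokens with
multiplicity preserved.  Sentence boundaries come from the upstream
concept-mapping step and are never re-derived here.

Two corpus serialisations are supported:

* line-based text — a header line ``#DOC<TAB>doc_id`` followed by one line
  per sentence (space-separated tokens; a whitespace-only line encodes an
  empty sentence); a zero-length line terminates the document;
* JSON-Lines — one object ``{"doc_id": ..., "sentences": [[tok, ...], ...]}``
  per line.

This module also ingests MetaMap-style fielded output (phrase candidates
with integer match scores, 0-1000) into a :class:`ConceptDocument`,
keeping every candidate concept whose score exceeds a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Sentence",
    "ConceptDocument",
    "Corpus",
    "Query",
    "MetaMapCandidate",
    "MetaMapMapping",
    "CorpusFormatError",
    "validate_token",
    "read_corpus",
    "write_corpus",
    "parse_metamap_output",
    "df_index",
]

#: A sentence is an ordered list of concept tokens, multiplicity preserved.
Sentence = list

_WHITESPACE = set(" \t\r\n\v\f")

#: Default MetaMap candidate-score cutoff; candidates must score strictly
#: above this to be extracted.
DEFAULT_SCORE_THRESHOLD = 500


class CorpusFormatError(ValueError):
    """Raised when a corpus or MetaMap file does not conform to its format."""


def validate_token(token: str) -> str:
    """Check that *token* is a legal concept token (non-empty, no whitespace)."""
    if not isinstance(token, str) or not token:
        raise ValueError(f"concept token must be a non-empty string, got {token!r}")
    if any(ch in _WHITESPACE for ch in token):
        raise ValueError(f"concept token may not contain whitespace: {token!r}")
    return token


@dataclass
class ConceptDocument:
    """A document as an ordered list of concept sentences.

    Parameters
    ----------
    doc_id:
        Opaque document identifier, unique within a corpus.
    sentences:
        Ordered sentences; each an ordered list of concept tokens.  Empty
        sentences are legal (a source sentence that mapped to no concepts)
        and are retained: they still count as transactions during
        association mining.
    """

    doc_id: str
    sentences: list

    def __post_init__(self) -> None:
        if not isinstance(self.doc_id, str) or not self.doc_id:
            raise ValueError("doc_id must be a non-empty string")
        for sent in self.sentences:
            for tok in sent:
                validate_token(tok)

    def tokens(self) -> Iterator[str]:
        """All tokens flattened in order, multiplicity preserved."""
        for sent in self.sentences:
            yield from sent

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def concepts(self) -> set:
        """The set of unique concepts in the document (union over sentences)."""
        out: set = set()
        for sent in self.sentences:
            out.update(sent)
        return out


@dataclass
class Corpus:
    """A document collection with its document-frequency index.

    ``df`` maps every concept occurring in the collection to the number of
    documents containing it (presence, not multiplicity).  It is built at
    construction and must stay consistent with ``documents``.
    """

    documents: list
    df: dict = field(init=False)
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError("a corpus needs at least one document")
        self._by_id = {}
        for doc in self.documents:
            if doc.doc_id in self._by_id:
                raise CorpusFormatError(f"duplicate doc_id: {doc.doc_id!r}")
            self._by_id[doc.doc_id] = doc
        self.df = df_index(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[ConceptDocument]:
        return iter(self.documents)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __getitem__(self, doc_id: str) -> ConceptDocument:
        return self._by_id[doc_id]

    def document_frequency(self, concept: str) -> int:
        return self.df.get(concept, 0)


class Query:
    """A topic query: a set of unique concept tokens.

    Duplicates collapse at construction; at least one concept is required.
    Iteration order is sorted, so a query iterates deterministically.
    """

    __slots__ = ("concepts",)

    def __init__(self, concepts: Iterable) -> None:
        toks = frozenset(validate_token(t) for t in concepts)
        if not toks:
            raise ValueError("a query needs at least one concept")
        self.concepts = toks

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.concepts))

    def __contains__(self, token: str) -> bool:
        return token in self.concepts

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Query) and self.concepts == other.concepts

    def __hash__(self) -> int:
        return hash(self.concepts)

    def __repr__(self) -> str:
        return f"Query({sorted(self.concepts)!r})"


@dataclass(frozen=True)
class MetaMapCandidate:
    """One candidate concept for a phrase: match score, CUI, name, semantic type."""

    score: int
    concept: str
    name: str
    semantic_type: str = ""


@dataclass
class MetaMapMapping:
    """A phrase together with its candidate concept mappings."""

    phrase: str
    candidates: list

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("a recorded mapping needs at least one candidate")
        for cand in self.candidates:
            if cand.score <= 0:
                raise ValueError(f"candidate scores must be positive: {cand!r}")


def df_index(documents: Iterable) -> dict:
    """Document frequency of every concept: in how many documents it appears.

    Counts document membership, not token multiplicity; concepts absent from
    every document are absent from the index.
    """
    docs = list(documents)
    if not docs:
        raise ValueError("df_index needs at least one document")
    index: dict = {}
    for doc in docs:
        for concept in doc.concepts:
            index[concept] = index.get(concept, 0) + 1
    return index


# ---------------------------------------------------------------------------
# corpus serialisation
# ---------------------------------------------------------------------------


def read_corpus(path) -> Corpus:
    """Read a corpus from the line-based text format or JSON-Lines.

    The format is sniffed from the first non-blank character: ``{`` selects
    JSON-Lines, otherwise the ``#DOC`` text format is expected.  Errors name
    the offending line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if not stripped:
        raise CorpusFormatError("empty corpus")
    if stripped[0] == "{":
        return _read_jsonl(text)
    return _read_text(text)


def _read_jsonl(text: str) -> Corpus:
    documents = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            documents.append(
                ConceptDocument(obj["doc_id"], [list(s) for s in obj["sentences"]])
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise CorpusFormatError(f"line {lineno}: malformed document record ({exc})")
    if not documents:
        raise CorpusFormatError("empty corpus")
    return Corpus(documents)


def _read_text(text: str) -> Corpus:
    documents = []
    doc_id = None
    sentences: list = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if line == "":  # zero-length line terminates the current document
            if doc_id is not None:
                documents.append(ConceptDocument(doc_id, sentences))
                doc_id, sentences = None, []
            continue
        if line.startswith("#DOC"):
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise CorpusFormatError(f"line {lineno}: malformed #DOC header")
            if doc_id is not None:
                documents.append(ConceptDocument(doc_id, sentences))
            doc_id, sentences = parts[1], []
            continue
        if doc_id is None:
            raise CorpusFormatError(f"line {lineno}: sentence outside any document")
        try:
            sentences.append(line.split())
        except ValueError as exc:  # pragma: no cover - split never raises
            raise CorpusFormatError(f"line {lineno}: {exc}")
    if doc_id is not None:
        documents.append(ConceptDocument(doc_id, sentences))
    if not documents:
        raise CorpusFormatError("empty corpus")
    return Corpus(documents)


def write_corpus(corpus: Corpus, path, fmt: str = "text") -> None:
    """Write *corpus* so that :func:`read_corpus` restores it structurally.

    ``fmt="text"`` writes the ``#DOC`` line format (an empty sentence is
    written as a single-space line); ``fmt="jsonl"`` writes JSON-Lines.
    """
    path = Path(path)
    if fmt == "text":
        chunks = []
        for doc in corpus:
            lines = [f"#DOC\t{doc.doc_id}"]
            for sent in doc.sentences:
                lines.append(" ".join(sent) if sent else " ")
            chunks.append("\n".join(lines))
        path.write_text("\n\n".join(chunks) + "\n", encoding="utf-8")
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                fh.write(
                    json.dumps({"doc_id": doc.doc_id, "sentences": doc.sentences})
                    + "\n"
                )
    else:
        raise ValueError(f"unknown corpus format: {fmt!r}")


# ---------------------------------------------------------------------------
# MetaMap-style ingestion
# ---------------------------------------------------------------------------


def parse_metamap_output(
    text: str,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
    doc_id: str = "metamap",
) -> ConceptDocument:
    """Extract a concept document from MetaMap-style fielded output.

    The dialect mirrors MetaMap's per-phrase candidate listing::

        #SENT
        #PHRASE<TAB>phrase text
        score<TAB>CUI<TAB>concept name<TAB>[semantic type]

    Every candidate scoring strictly above ``score_threshold`` contributes
    its concept once per phrase occurrence (a phrase that occurs m times in
    the article appears as m ``#PHRASE`` blocks and contributes its concepts
    m times).  Within one phrase occurrence a concept reached through two
    candidates is counted once.  Sentences that map to no concepts yield
    empty sentences; a document with no ``#SENT`` markers is empty (not an
    error).
    """
    if score_threshold < 0:
        raise ValueError("score_threshold must be >= 0")
    sentences: list = []
    current: list | None = None
    phrase_concepts: list | None = None
    phrase_seen: set | None = None

    def close_phrase() -> None:
        nonlocal phrase_concepts, phrase_seen
        if phrase_concepts is not None:
            current.extend(phrase_concepts)
        phrase_concepts, phrase_seen = None, None

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#SENT"):
            close_phrase()
            current = []
            sentences.append(current)
            continue
        if line.startswith("#PHRASE"):
            if current is None:
                raise CorpusFormatError(f"line {lineno}: #PHRASE before any #SENT")
            close_phrase()
            phrase_concepts, phrase_seen = [], set()
            continue
        # candidate line
        if phrase_concepts is None:
            raise CorpusFormatError(f"line {lineno}: candidate outside any phrase")
        parts = line.split("\t")
        if len(parts) < 2:
            raise CorpusFormatError(f"line {lineno}: unparseable candidate line")
        try:
            score = int(parts[0])
        except ValueError:
            raise CorpusFormatError(
                f"line {lineno}: candidate score is not an integer: {parts[0]!r}"
            )
        concept = parts[1].strip()
        if not concept:
            raise CorpusFormatError(f"line {lineno}: empty concept identifier")
        if score > score_threshold and concept not in phrase_seen:
            phrase_seen.add(concept)
            phrase_concepts.append(concept)
    close_phrase()
    return ConceptDocument(doc_id, sentences)
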