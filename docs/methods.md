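# Methods

This note documents the models implemented in `conceptrf`, the parameter
choices, the synthetic data the tests run on, and the numerical
conventions. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Pipeline

1. **Concept documents.** Every article is an ordered list of sentences,
   each a list of concept tokens with multiplicity preserved. Sentence
   boundaries are fixed upstream at concept-mapping time and are never
   re-derived. Empty sentences are *retained*: during association mining
   they are transactions with zero counts, and dropping them would silently
   change the transaction count `N`.

2. **MetaMap-style ingestion.** The parser reads a fielded candidate
   listing (`#SENT` / `#PHRASE` / `score<TAB>CUI<TAB>name<TAB>[type]`).
   A candidate contributes its concept when its score is strictly greater
   than the threshold (default 500, configurable). A phrase occurring m
   times contributes its concepts m times; within a single phrase
   occurrence a concept reachable through two candidates is deduplicated —
   two lexical variants mapping to the same CUI are one mention, not two.

3. **Initial ranking.** Accumulative TF-IDF over the query's concepts.
   The TF denominator is the document's flattened token count
   (multiplicity, not unique-concept count). IDF uses log base 10; the
   ranking is base-invariant, so the base only fixes reported score
   values. A query concept absent from the corpus contributes 0 (it cannot
   discriminate documents it never appears in). Ties break on ascending
   doc_id everywhere, so all rankings are deterministic.

4. **Weighted-interest mining.** Counts are membership-based within a
   sentence (within-sentence multiplicity is ignored for both query
   concepts and the candidate). `N` is the sentence count of the
   transaction set actually being mined: the pooled feedback for `Z`, a
   document's own sentence count when profiling that document. When
   `f_Q^w = 0` the measure is defined as 0 for every concept rather than
   dividing by zero. Query concepts are eligible profile members. Profiles
   rank *all* concepts and truncate at `k` with no floor at `I^w = 1`;
   concepts below the independence baseline simply rank low. Profile ties
   break on higher `f_{Qc}^w` (more joint evidence first), then ascending
   token.

5. **RBO re-ranking.** The truncated form: outer factor `(1 − φ)`, sum over
   depths 1..k, no extrapolated tail. Consequently two identical length-k
   lists score `1 − φ^k`, not 1 — accepted as-is, since only the ordering
   matters for retrieval. Lists shorter than the current depth contribute
   their whole prefix. Arithmetic is kept at full precision internally;
   rounding to two decimals happens only at reporting time. Document
   profiles depend on the query but not on the feedback, so they are mined
   once per (corpus, query) and truncated to any `k` (see
   `rbo.profile_corpus`).

6. **Retention.** The selected documents missing from the next round's
   top-χ replace its lowest-ranked unselected entries, both walked from the
   end, skipping entries that are themselves selected. Under the
   preconditions (equal window lengths, selection drawn from the previous
   window) the replacements always fit; the "cannot retain" error can only
   fire on degenerate inputs such as duplicated selections.

7. **Sessions.** Each round's transaction set is that round's selection
   only; earlier selections stay in the history for audit but are not
   pooled forward. Pooling across rounds (or unions) is a plausible
   alternative; per-round pooling was chosen because each feedback
   submission expresses the user's *current* reading of the results.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `k` | 30 | profile depth; 20–30 works well, very small or very large k degrades re-ranking (too little signal vs. off-topic concepts admitted) |
| `φ` (`phi`) | 0.9 | RBO weight decay; smaller = more top-weighted |
| `χ` (`chi`) | 10 | top-list size the user reviews per round |
| `score_threshold` | 500 | strict lower bound on MetaMap candidate scores |

## Evaluation conventions

Average precision at cutoff N is computed over the top-N list only, with
denominator equal to the number of relevant documents retrieved within N
(0 when none). This pairs MAP@N with counts of relevant documents in the
top N; cutoff-AP denominators vary across the literature, so the
convention is stated here explicitly. Topics whose current top-χ holds no
relevant document cannot produce feedback; the simulated user stops there
and such topics are excluded from later-round MAP. Qrels grades are
encoded 0 = NOT, 1 = POSSIBLY, 2 = DEFINITELY, with binary relevance
derived under `possibly+` or `definitely-only` gold standards.

## Synthetic corpus generator

The generator emulates a concept-mapped collection with planted structure
so the full pipeline is testable offline; it does not model any real
document collection.

* **Background**: tokens drawn from a Zipf-like distribution
  (`p ∝ rank^−1.1`) over a 2000-concept vocabulary; 5–200 sentences per
  document, 2–20 tokens per sentence.
* **Query and signal concepts** are drawn disjointly from the
  mid-frequency band (ranks 20–200): frequent enough to occur naturally,
  rare enough to discriminate.
* **Relevant documents** contain *signal sentences* at the co-occurrence
  rate (default 0.6): one or more query concepts together with 1–3
  concepts from a 6-concept signal set, padded with concepts from the
  common head (top 20 ranks) of the vocabulary. The padding choice is
  deliberate: a sentence genuinely about the topic mixes topical concepts
  with ubiquitous ones, whereas a *rare* concept co-occurring once with
  the query is indistinguishable, under any lift-style measure, from
  topical signal — a single co-mention saturates `I^w`. Salting topical
  sentences with rare background would therefore bury the planted signal
  under singleton noise in every profile and leave nothing for feedback
  to learn.
* **Distractor documents** (default 15) mention query concepts at the same
  per-sentence rate as relevant documents but amid arbitrary full-vocabulary
  content. They emulate keyword-matching but off-topic articles — the
  situation relevance feedback exists to fix. Without them the initial
  TF-IDF ranking solves a planted corpus outright and the feedback round
  has no headroom.
* **Anchor document**: one designated relevant document carries every
  query concept in each signal sentence (and, independently of the
  co-occurrence rate, occasional query mentions), guaranteeing a top-tier
  initial score so a simulated user always has at least one relevant
  document to select — including in the zero-co-occurrence negative
  control, where feedback must then yield no gain.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator`; regeneration is byte-identical.

What passing tests on this generator do **not** show: robustness to real
concept-mapping noise (MetaMap ambiguity, score calibration), to topic
drift within a document, to graded rather than planted relevance, or to
collection sizes beyond a few hundred documents. The directional results
(feedback improves MAP@10; intermediate k beats tiny k) are properties of
the planted-structure regime, demonstrated over 25 seeded corpora of 100
documents with 8 relevant ones — sizes chosen so the whole suite runs
quickly on one CPU while leaving the statistical pattern unambiguous.

## Numerical and degenerate-input conventions

* Exactness: association scores and RBO agree with brute-force oracles to
  1e-12 in the tests; no intermediate rounding anywhere.
* Empty document: TF is undefined (error); its A-TF-IDF is 0 and its
  profile is empty (RBO 0), so empty documents rank last without error.
* Empty sentence in the line-based corpus format is encoded as a
  whitespace-only line (a zero-length line terminates the document);
  JSON-Lines encodes it natively.
* `weighted_interest` for a concept absent from Z is an error (no rule
  exists), distinct from the `f_Q^w = 0` convention above.
* The corpus format sniffs JSON-Lines vs. the `#DOC` line format from the
  first non-blank character.

## Known limitations

* The lift-style measure is support-free: concepts occurring once in a
  high-`CNT(Q)` sentence reach the maximal `I^w`. On real collections a
  minimum-support floor or shrinkage may be warranted; it is not applied
  here because the implemented measure is the object of study.
* Truncated RBO is not a metric and never reaches 1; scores are only
  comparable at fixed `φ` and `k`.
* Live UMLS/MetaMap integration is out of scope; only the file-format
  parser is provided.
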