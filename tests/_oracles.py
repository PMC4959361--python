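"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the defining formulas with plain
loops and no imports from the package, so a bug in the library cannot hide
in its own oracle.
"""

import math
from itertools import count


def oracle_association_scores(query_concepts, sentences):
    """Per-concept (I^w, f_Q^w, f_c, f_{Qc}^w) by direct per-rule loops."""
    qset = set(query_concepts)
    n = len(sentences)
    all_concepts = sorted({c for s in sentences for c in s})
    f_q = 0.0
    for s in sentences:
        present = [c for c in qset if c in s]
        f_q += len(present) / len(qset)
    out = {}
    for concept in all_concepts:
        f_c = 0
        f_joint = 0.0
        for s in sentences:
            cnt_c = 1 if concept in s else 0
            cnt_q = len([c for c in qset if c in s]) / len(qset)
            f_c += cnt_c
            f_joint += cnt_q * cnt_c
        iw = 0.0 if f_q == 0 else n * f_joint / (f_q * f_c)
        out[concept] = (iw, f_q, f_c, f_joint)
    return out


def oracle_a_tf_idf(query_concepts, doc_sentences, corpus_sentences_by_id):
    """A-TF-IDF by a literal double loop over query concepts."""
    tokens = [t for s in doc_sentences for t in s]
    if not tokens:
        return 0.0
    n_docs = len(corpus_sentences_by_id)
    score = 0.0
    for concept in query_concepts:
        tf = tokens.count(concept) / len(tokens)
        df = sum(
            1
            for sentences in corpus_sentences_by_id.values()
            if any(concept in s for s in sentences)
        )
        idf = 0.0 if df == 0 else math.log10(n_docs / df)
        score += tf * idf
    return score


def oracle_rbo(a, b, phi, k):
    """Truncated RBO by slicing prefixes at every depth."""
    total = 0.0
    for depth in range(1, k + 1):
        overlap = len(set(a[:depth]) & set(b[:depth]))
        total += phi ** (depth - 1) * overlap / depth
    return (1 - phi) * total


def oracle_retain(prev_top, selected, next_top):
    """Literal simulation of the retention walk, position by position."""
    r = set(selected)
    xi = [d for d in selected if d not in next_top]
    out = list(next_top)
    positions = [i for i in range(len(out)) if out[i] not in r]
    for doc, pos in zip(reversed(xi), reversed(positions[len(positions) - len(xi):])):
        out[pos] = doc
    return out


def oracle_average_precision(doc_ids, relevant, cutoff):
    """AP by explicit enumeration of precision at each relevant rank."""
    found = []
    for rank, doc in zip(count(1), doc_ids[:cutoff]):
        if doc in relevant:
            hits = sum(1 for d in doc_ids[:rank] if d in relevant)
            found.append(hits / rank)
    return sum(found) / len(found) if found else 0.0
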