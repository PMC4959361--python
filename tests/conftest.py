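import random

import pytest

from conceptrf import ConceptDocument, Corpus, Query

# The five-sentence worked example document used throughout the docs:
# six unique concepts, 25 tokens.
EXAMPLE_SENTENCES = [
    ["1", "3", "4", "3", "5"],
    ["4", "5", "5", "1"],
    ["3", "5", "1", "3", "1", "6"],
    ["1", "5", "4", "4", "1"],
    ["5", "2", "4", "6", "2"],
]

# Synthetic stand-in for a MetaMap candidate listing: two phrases whose
# candidates scoring strictly above 500 number seven in total, plus two
# below-threshold candidates that the filter must drop.  The phrases and
# concept names are invented; only the fielded layout and score semantics
# matter.
METAMAP_FIXTURE = """\
#SENT
#PHRASE\tcathepsin d
861\tC0006814\tCathepsin D\t[Amino Acid, Peptide, or Protein]
861\tC1412472\tCTSD gene\t[Gene or Genome]
694\tC0002364\tAspartic proteinase\t[Enzyme]
400\tC0599791\tProteinase\t[Enzyme]
#SENT
#PHRASE\talzheimer's disease
1000\tC0002395\tAlzheimer's Disease\t[Disease or Syndrome]
827\tC0276496\tFamilial Alzheimer Disease\t[Disease or Syndrome]
660\tC0333463\tSenile Plaque\t[Anatomical Abnormality]
588\tC0011269\tDementia\t[Mental or Behavioral Dysfunction]
333\tC0027651\tNeoplasm\t[Neoplastic Process]
"""


@pytest.fixture
def example_doc():
    return ConceptDocument("d1", [list(s) for s in EXAMPLE_SENTENCES])


@pytest.fixture
def example_query():
    return Query(["3", "2", "6"])


def random_sentences(rng, max_sentences=8, max_tokens=10, vocab=40):
    n_sent = rng.randint(1, max_sentences)
    return [
        [str(rng.randint(1, vocab)) for _ in range(rng.randint(0, max_tokens))]
        for _ in range(n_sent)
    ]


def random_corpus(seed, n_docs=20, max_sentences=8, max_tokens=10, vocab=40):
    rng = random.Random(seed)
    docs = [
        ConceptDocument(f"d{i:03d}", random_sentences(rng, max_sentences, max_tokens, vocab))
        for i in range(n_docs)
    ]
    return Corpus(docs)


def random_query(seed, size=3, vocab=40):
    rng = random.Random(seed + 10_000)
    return Query({str(rng.randint(1, vocab)) for _ in range(size)} or {"1"})
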