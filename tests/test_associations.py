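import random

import pytest

from conceptrf import (
    ConceptDocument,
    FeedbackSet,
    KProfile,
    Query,
    build_k_profile,
    mine_associations,
    weighted_interest,
)
from conceptrf.associations import (
    binary_count_concept,
    frequency_concept,
    joint_partial_count,
    partial_count_query,
    weighted_frequency_query,
    weighted_joint_frequency,
)
from _oracles import oracle_association_scores
from conftest import random_sentences


@pytest.fixture
def example_z(example_doc):
    return FeedbackSet.from_documents([example_doc])


class TestPerSentenceCounts:
    def test_partial_count_first_sentence(self, example_query, example_doc):
        assert partial_count_query(example_query, example_doc.sentences[0]) == pytest.approx(1 / 3)

    def test_partial_count_fifth_sentence(self, example_query, example_doc):
        assert partial_count_query(example_query, example_doc.sentences[4]) == pytest.approx(2 / 3)

    def test_fully_contained_query_counts_one(self, example_query):
        assert partial_count_query(example_query, ["2", "3", "6", "9"]) == 1.0

    def test_binary_count_presence(self, example_doc):
        assert binary_count_concept("1", example_doc.sentences[0]) == 1
        assert binary_count_concept("1", example_doc.sentences[4]) == 0
        assert binary_count_concept("1", []) == 0

    def test_joint_count_is_the_product(self, example_query, example_doc):
        assert joint_partial_count(example_query, "1", example_doc.sentences[0]) == pytest.approx(1 / 3)
        assert joint_partial_count(example_query, "1", example_doc.sentences[2]) == pytest.approx(2 / 3)
        assert joint_partial_count(example_query, "1", ["9"]) == 0.0

    def test_membership_ignores_multiplicity(self, example_query):
        # concept 2 appears twice in the sentence; counts stay membership-based
        assert partial_count_query(example_query, ["2", "2", "9"]) == pytest.approx(1 / 3)
        assert binary_count_concept("2", ["2", "2"]) == 1


class TestFrequencies:
    def test_worked_example_sums(self, example_query, example_z):
        assert weighted_frequency_query(example_query, example_z) == pytest.approx(5 / 3)
        assert frequency_concept("1", example_z) == 4
        assert weighted_joint_frequency(example_query, "1", example_z) == pytest.approx(1.0)

    def test_disjoint_query_has_zero_weighted_frequency(self, example_z):
        assert weighted_frequency_query(Query(["77"]), example_z) == 0.0

    def test_absent_concept_has_zero_frequency(self, example_query, example_z):
        assert frequency_concept("77", example_z) == 0
        assert weighted_joint_frequency(example_query, "77", example_z) == 0.0

    def test_random_z_matches_loop_oracle(self, example_query):
        rng = random.Random(42)
        sentences = random_sentences(rng, max_sentences=30)
        z = FeedbackSet(["z"], sentences)
        oracle = oracle_association_scores(sorted(example_query.concepts), sentences)
        if oracle:
            _, f_q, _, _ = next(iter(oracle.values()))
            assert weighted_frequency_query(example_query, z) == pytest.approx(f_q, abs=1e-12)
        for concept, (_, _, f_c, f_joint) in oracle.items():
            assert frequency_concept(concept, z) == f_c
            assert weighted_joint_frequency(example_query, concept, z) == pytest.approx(
                f_joint, abs=1e-12
            )


class TestWeightedInterest:
    def test_worked_example_value(self, example_query, example_z):
        assert weighted_interest(example_query, "1", example_z) == pytest.approx(0.75)

    def test_query_disjoint_from_z_gives_zero(self, example_z):
        assert weighted_interest(Query(["77"]), "1", example_z) == 0.0

    def test_concept_absent_from_z_is_an_error(self, example_query, example_z):
        with pytest.raises(ValueError, match="not in feedback"):
            weighted_interest(example_query, "77", example_z)

    def test_all_example_concepts_match_brute_force(self, example_query, example_z):
        oracle = oracle_association_scores(
            sorted(example_query.concepts), example_z.sentences
        )
        for concept, (iw, _, _, _) in oracle.items():
            assert weighted_interest(example_query, concept, example_z) == pytest.approx(
                iw, abs=1e-12
            )

    def test_doubling_z_leaves_interest_unchanged(self, example_query, example_z):
        doubled = FeedbackSet(["z", "z2"], example_z.sentences * 2)
        for concept in sorted(example_z.unique_concepts()):
            assert weighted_interest(example_query, concept, doubled) == pytest.approx(
                weighted_interest(example_query, concept, example_z), abs=1e-12
            )

    def test_singleton_query_reduces_to_classic_lift(self):
        rng = random.Random(7)
        sentences = random_sentences(rng, max_sentences=20, vocab=10)
        z = FeedbackSet(["z"], sentences)
        q = Query(["1"])
        n = z.transaction_count
        f_x = sum(1 for s in sentences if "1" in s)
        for concept in sorted(z.unique_concepts()):
            f_y = sum(1 for s in sentences if concept in s)
            f_xy = sum(1 for s in sentences if "1" in s and concept in s)
            expected = 0.0 if f_x == 0 else n * f_xy / (f_x * f_y)
            assert weighted_interest(q, concept, z) == pytest.approx(expected, abs=1e-12)


class TestMineAssociations:
    def test_example_document_yields_six_rules(self, example_query, example_z):
        scores = mine_associations(example_query, example_z)
        assert len(scores) == 6
        assert {s.concept for s in scores} == {"1", "2", "3", "4", "5", "6"}

    def test_rule_with_perfect_co_occurrence(self):
        q = Query(["a", "b"])
        z = FeedbackSet(["z"], [["a", "b", "x"], ["c"], ["d"]])
        scores = {s.concept: s for s in mine_associations(q, z)}
        # one sentence equals Q u {x}: I^w = N * 1 / (1 * 1) = N
        assert scores["x"].weighted_interest == pytest.approx(z.transaction_count)

    def test_matches_per_concept_calls(self, example_query, example_z):
        for score in mine_associations(example_query, example_z):
            assert score.weighted_interest == pytest.approx(
                weighted_interest(example_query, score.concept, example_z), abs=1e-12
            )

    def test_empty_z_is_an_error(self, example_query):
        with pytest.raises(ValueError, match="empty"):
            mine_associations(example_query, FeedbackSet([], []))

    def test_joint_frequency_bounds(self, example_query):
        rng = random.Random(13)
        for _ in range(20):
            z = FeedbackSet(["z"], random_sentences(rng, max_sentences=25))
            for s in mine_associations(example_query, z):
                assert 0.0 <= s.f_joint_weighted <= s.f_q_weighted + 1e-12
                assert s.f_joint_weighted <= s.f_c + 1e-12

    def test_order_is_descending_with_deterministic_ties(self, example_query):
        rng = random.Random(99)
        z = FeedbackSet(["z"], random_sentences(rng, max_sentences=25))
        scores = mine_associations(example_query, z)
        keys = [(-s.weighted_interest, -s.f_joint_weighted, s.concept) for s in scores]
        assert keys == sorted(keys)


class TestKProfile:
    def test_full_profile_ordered_by_interest(self, example_query, example_z):
        profile = build_k_profile(example_query, example_z, k=10)
        oracle = oracle_association_scores(
            sorted(example_query.concepts), example_z.sentences
        )
        assert len(profile) == 6
        iws = [iw for _, iw in profile.concepts]
        assert iws == sorted(iws, reverse=True)
        for concept, iw in profile.concepts:
            assert iw == pytest.approx(oracle[concept][0], abs=1e-12)

    def test_k_one_keeps_only_the_argmax(self, example_query, example_z):
        profile = build_k_profile(example_query, example_z, k=1)
        full = build_k_profile(example_query, example_z, k=10)
        assert profile.tokens == full.tokens[:1]

    def test_truncation_never_pads(self, example_query):
        doc = ConceptDocument("d", [["a", "b"], ["c"]])
        profile = build_k_profile(example_query, doc, k=30)
        assert len(profile) == 3

    def test_document_profiling_uses_own_sentences(self, example_query, example_doc, example_z):
        assert (
            build_k_profile(example_query, example_doc, k=6).tokens
            == build_k_profile(example_query, example_z, k=6).tokens
        )

    def test_empty_input_gives_empty_profile(self, example_query):
        profile = build_k_profile(example_query, FeedbackSet([], []), k=5)
        assert len(profile) == 0

    def test_json_round_trip(self, example_query, example_z):
        profile = build_k_profile(example_query, example_z, k=4)
        back = KProfile.from_json(profile.to_json())
        assert back.query == profile.query
        assert back.k == profile.k
        assert back.tokens == profile.tokens
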