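import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chunktrack import stimuli
from chunktrack.stimuli import (
    Category,
    Condition,
    OrderType,
    StimulusSequence,
    Subcategory,
    build_condition_block,
    build_vocabulary,
    fill_words,
    make_alternating_sequence,
    make_outlier,
    make_random_sequence,
    validate_sequence,
)


class TestVocabulary:
    def test_counts(self):
        vocab = build_vocabulary(1)
        assert len(vocab) == 240
        for sub in Subcategory:
            assert len(vocab.by_subcategory(sub)) == 60

    def test_unique_ids(self):
        vocab = build_vocabulary(1)
        ids = [t.word_id for t in vocab.tokens]
        assert len(set(ids)) == 240

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_counts_seed_independent(self, seed):
        vocab = build_vocabulary(seed)
        assert len(vocab.by_category(Category.LIVING)) == 120
        assert len(vocab.by_category(Category.NONLIVING)) == 120

    def test_category_partition(self):
        vocab = build_vocabulary(2)
        living = set(vocab.by_category(Category.LIVING))
        nonliving = set(vocab.by_category(Category.NONLIVING))
        assert living | nonliving == set(vocab.tokens)
        assert not living & nonliving

    def test_subcategory_category_invariant(self):
        with pytest.raises(ValueError):
            stimuli.WordToken("x", Category.LIVING, Subcategory.MANIPULATABLE)


class TestAlternating:
    def test_same_category_pattern(self):
        seq = make_alternating_sequence(Condition.SAME)
        assert seq.categories == "NNLL" * 6
        assert len(seq.categories) == 24
        assert seq.order_type is OrderType.ALTERNATING

    def test_different_category_pattern(self):
        seq = make_alternating_sequence(Condition.DIFFERENT)
        assert seq.categories == "NLLN" * 6

    def test_shift_relation(self):
        # dropping the first word of the different-category pattern leaves
        # a sequence whose 11 complete chunks are all same-category-valid
        diff = make_alternating_sequence(Condition.DIFFERENT).categories
        shifted = diff[1:-1]
        chunks = [shifted[i : i + 2] for i in range(0, 22, 2)]
        assert all(c[0] == c[1] for c in chunks)

    def test_onset_grid(self):
        seq = make_alternating_sequence(Condition.SAME)
        assert np.allclose(seq.word_onsets, np.arange(0, 12, 0.5))
        assert seq.duration == 12.0


class TestRandomOrder:
    def test_valid_chunks_only(self, rng):
        for cond, allowed in [
            (Condition.SAME, {"LL", "NN"}),
            (Condition.DIFFERENT, {"NL", "LN"}),
        ]:
            for _ in range(50):
                seq = make_random_sequence(cond, rng)
                assert {c.categories for c in seq.chunks} <= allowed

    def test_chunk_draw_fraction(self, rng):
        # binomial oracle: fraction of LL chunks over many i.i.d. draws
        n_seq = 1000
        n_ll = sum(
            sum(c.categories == "LL" for c in make_random_sequence(Condition.SAME, rng).chunks)
            for _ in range(n_seq)
        )
        n = n_seq * 12
        se = np.sqrt(0.25 / n)
        assert abs(n_ll / n - 0.5) < 3 * se


class TestFillWords:
    def test_distinct_words_two_subcategories(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        assert len(set(seq.word_ids)) == 24
        assert len({w.subcategory for w in seq.words}) <= 2

    def test_all_living_pattern(self, vocabulary, rng):
        seq = StimulusSequence(Condition.SAME, OrderType.RANDOM, "L" * 24)
        filled = fill_words(seq, vocabulary, rng)
        assert len(set(filled.word_ids)) == 24
        assert len({w.subcategory for w in filled.words}) == 1

    def test_deterministic_under_seed(self, vocabulary):
        a = fill_words(
            make_alternating_sequence(Condition.SAME), vocabulary, np.random.default_rng(5)
        )
        b = fill_words(
            make_alternating_sequence(Condition.SAME), vocabulary, np.random.default_rng(5)
        )
        assert a.word_ids == b.word_ids

    def test_categories_match_pattern(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.DIFFERENT), vocabulary, rng)
        for w, c in zip(seq.words, seq.categories):
            assert w.category.value == c


class TestOutlier:
    @pytest.mark.parametrize("condition", list(Condition))
    def test_exactly_two_invalid(self, condition, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(condition), vocabulary, rng)
        out = make_outlier(seq, rng)
        assert out.is_outlier
        assert len(out.invalid_chunk_indices()) == 2

    def test_invalid_chunk_types(self, vocabulary, rng):
        same = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        out = make_outlier(same, rng)
        bad = [out.chunks[i].categories for i in out.invalid_chunk_indices()]
        assert set(bad) <= {"LN", "NL"}
        diff = fill_words(make_alternating_sequence(Condition.DIFFERENT), vocabulary, rng)
        out = make_outlier(diff, rng)
        bad = [out.chunks[i].categories for i in out.invalid_chunk_indices()]
        assert set(bad) <= {"LL", "NN"}

    def test_other_chunks_untouched(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        out = make_outlier(seq, rng)
        touched = set(out.invalid_chunk_indices())
        for i in range(12):
            if i not in touched:
                assert out.chunks[i].categories == seq.chunks[i].categories
                assert out.chunks[i].words == seq.chunks[i].words

    def test_swap_is_an_l_n_exchange(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        out = make_outlier(seq, rng)
        changed = [i for i in range(24) if seq.categories[i] != out.categories[i]]
        assert len(changed) == 2
        assert {seq.categories[i] for i in changed} == {"L", "N"}
        assert sorted(seq.word_ids) == sorted(out.word_ids)

    def test_double_outlier_rejected(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        out = make_outlier(seq, rng)
        with pytest.raises(ValueError):
            make_outlier(out, rng)


class TestConditionBlock:
    @pytest.mark.parametrize("condition", list(Condition))
    def test_composition(self, condition, vocabulary, rng):
        block = build_condition_block(condition, vocabulary, rng)
        assert len(block.sequences) == 60
        assert len(block.outlier_sequences()) == 16
        assert len(block.normal_sequences()) == 44
        for order in OrderType:
            normal = [
                s for s in block.normal_sequences() if s.order_type is order
            ]
            outlier = [
                s for s in block.outlier_sequences() if s.order_type is order
            ]
            assert len(normal) == 22
            assert len(outlier) == 8

    def test_presentation_order_is_permutation(self, vocabulary, rng):
        block = build_condition_block(Condition.SAME, vocabulary, rng)
        assert sorted(block.presentation_order) == list(range(60))
        assert len(block.presented) == 60

    def test_validity_bookkeeping(self, vocabulary, rng):
        block = build_condition_block(Condition.DIFFERENT, vocabulary, rng)
        assert all(validate_sequence(s) for s in block.sequences)

    def test_counts_seed_independent(self, vocabulary):
        for seed in (3, 4):
            block = build_condition_block(
                Condition.SAME, vocabulary, np.random.default_rng(seed)
            )
            assert len(block.outlier_sequences()) == 16


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), condition=st.sampled_from(list(Condition)))
def test_random_sequences_always_valid(seed, condition):
    rng = np.random.default_rng(seed)
    seq = make_random_sequence(condition, rng)
    assert not seq.invalid_chunk_indices()
    assert validate_sequence(seq)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), condition=st.sampled_from(list(Condition)))
def test_outliers_always_fail_with_two_chunks(seed, condition):
    rng = np.random.default_rng(seed)
    seq = make_random_sequence(condition, rng)
    out = make_outlier(seq, rng)
    assert len(out.invalid_chunk_indices()) == 2
    assert validate_sequence(out)


class TestSerialization:
    def test_json_round_trip(self, vocabulary, rng):
        seqs = [
            fill_words(make_random_sequence(Condition.SAME, rng), vocabulary, rng)
            for _ in range(3)
        ]
        text = stimuli.sequences_to_json(seqs)
        back = stimuli.sequences_from_json(text, vocabulary)
        assert [s.categories for s in back] == [s.categories for s in seqs]
        assert [s.word_ids for s in back] == [s.word_ids for s in seqs]
        json.loads(text)  # valid JSON

    def test_event_table(self, vocabulary, rng):
        seq = fill_words(make_alternating_sequence(Condition.SAME), vocabulary, rng)
        table = stimuli.event_table([seq])
        assert len(table) == 24
        assert np.allclose(table["onset_s"], np.arange(0, 12, 0.5))
        assert table["chunk_onset"].sum() == 12
        assert table["chunk_index"].nunique() == 12
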