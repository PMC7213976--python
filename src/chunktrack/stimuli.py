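"""Symbolic stimulus-sequence generation.

Sequences are built from two-word chunks of living (``L``) and nonliving
(``N``) nouns. Each word lasts 0.5 s, each chunk 1 s, each sequence 12 s
(24 words, 12 chunks). The *same-category* condition admits the chunks
``LL``/``NN``; the *different-category* condition admits ``NL``/``LN``.
Word identities are opaque synthetic tokens — only category structure and
timing feed any downstream computation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WORD_DURATION = 0.5
WORDS_PER_CHUNK = 2
CHUNKS_PER_SEQUENCE = 12
WORDS_PER_SEQUENCE = CHUNKS_PER_SEQUENCE * WORDS_PER_CHUNK
SEQUENCE_DURATION = WORDS_PER_SEQUENCE * WORD_DURATION
WORD_RATE = 1.0 / WORD_DURATION
CHUNK_RATE = 1.0 / (WORDS_PER_CHUNK * WORD_DURATION)
POOL_SIZE = 60

#: Sequences per condition block and the outlier composition of a block.
SEQUENCES_PER_ORDER = 30
OUTLIERS_PER_ORDER = 8


class Category(str, enum.Enum):
    LIVING = "L"
    NONLIVING = "N"


class Subcategory(str, enum.Enum):
    ANIMAL = "animal"
    PLANT = "plant"
    MANIPULATABLE = "manipulatable"
    NON_MANIPULATABLE = "non_manipulatable"


SUBCATEGORY_CATEGORY: dict[Subcategory, Category] = {
    Subcategory.ANIMAL: Category.LIVING,
    Subcategory.PLANT: Category.LIVING,
    Subcategory.MANIPULATABLE: Category.NONLIVING,
    Subcategory.NON_MANIPULATABLE: Category.NONLIVING,
}

LIVING_SUBCATEGORIES = (Subcategory.ANIMAL, Subcategory.PLANT)
NONLIVING_SUBCATEGORIES = (Subcategory.MANIPULATABLE, Subcategory.NON_MANIPULATABLE)


class Condition(str, enum.Enum):
    SAME = "same_category"
    DIFFERENT = "different_category"


class OrderType(str, enum.Enum):
    ALTERNATING = "alternating"
    RANDOM = "random"


#: The two valid chunk spellings per condition.
VALID_CHUNKS: dict[Condition, tuple[str, str]] = {
    Condition.SAME: ("NN", "LL"),
    Condition.DIFFERENT: ("NL", "LN"),
}

#: Alternating-order phase convention: exactly the printed starting phases.
ALTERNATING_UNIT: dict[Condition, str] = {
    Condition.SAME: "NNLL",
    Condition.DIFFERENT: "NLLN",
}


@dataclass(frozen=True)
class WordToken:
    """A synthetic noun token with fixed 0.5 s duration."""

    word_id: str
    category: Category
    subcategory: Subcategory
    duration: float = WORD_DURATION

    def __post_init__(self) -> None:
        if SUBCATEGORY_CATEGORY[self.subcategory] is not self.category:
            raise ValueError(
                f"subcategory {self.subcategory} inconsistent with {self.category}"
            )


@dataclass(frozen=True)
class Vocabulary:
    """240 tokens: 60 per subcategory."""

    tokens: tuple[WordToken, ...]

    def by_subcategory(self, subcategory: Subcategory) -> tuple[WordToken, ...]:
        return tuple(t for t in self.tokens if t.subcategory is subcategory)

    def by_category(self, category: Category) -> tuple[WordToken, ...]:
        return tuple(t for t in self.tokens if t.category is category)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Chunk:
    """A two-word chunk; validity depends only on the category pair."""

    categories: str  # e.g. "NL"
    words: tuple[WordToken, WordToken] | None = None
    duration: float = WORDS_PER_CHUNK * WORD_DURATION

    def is_valid(self, condition: Condition) -> bool:
        a, b = self.categories
        if condition is Condition.SAME:
            return a == b
        return a != b


@dataclass(frozen=True)
class StimulusSequence:
    """A 12-chunk symbolic sequence.

    ``categories`` is the 24-letter L/N spelling; ``words`` is ``None`` for
    pattern-only sequences (before :func:`fill_words`).
    """

    condition: Condition
    order_type: OrderType
    categories: str
    words: tuple[WordToken, ...] | None = None
    is_outlier: bool = False

    def __post_init__(self) -> None:
        if len(self.categories) != WORDS_PER_SEQUENCE:
            raise ValueError(
                f"expected {WORDS_PER_SEQUENCE} category slots, got {len(self.categories)}"
            )
        if set(self.categories) - {"L", "N"}:
            raise ValueError(f"bad category letters in {self.categories!r}")
        if self.words is not None and len(self.words) != WORDS_PER_SEQUENCE:
            raise ValueError("words length must match category slots")

    @property
    def duration(self) -> float:
        return SEQUENCE_DURATION

    @property
    def word_onsets(self) -> np.ndarray:
        return np.arange(WORDS_PER_SEQUENCE) * WORD_DURATION

    @property
    def chunk_onsets(self) -> np.ndarray:
        return np.arange(CHUNKS_PER_SEQUENCE) * WORDS_PER_CHUNK * WORD_DURATION

    @property
    def chunks(self) -> tuple[Chunk, ...]:
        out = []
        for i in range(CHUNKS_PER_SEQUENCE):
            sl = slice(2 * i, 2 * i + 2)
            words = None if self.words is None else tuple(self.words[sl])
            out.append(Chunk(self.categories[sl], words))
        return tuple(out)

    def invalid_chunk_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.chunks) if not c.is_valid(self.condition)
        )

    @property
    def word_ids(self) -> tuple[str, ...] | None:
        if self.words is None:
            return None
        return tuple(w.word_id for w in self.words)


@dataclass(frozen=True)
class ConditionBlock:
    """One experimental block: 60 sequences, 16 of them outliers."""

    condition: Condition
    sequences: tuple[StimulusSequence, ...]
    presentation_order: tuple[int, ...] = field(default=())

    @property
    def presented(self) -> tuple[StimulusSequence, ...]:
        return tuple(self.sequences[i] for i in self.presentation_order)

    def normal_sequences(self) -> tuple[StimulusSequence, ...]:
        return tuple(s for s in self.sequences if not s.is_outlier)

    def outlier_sequences(self) -> tuple[StimulusSequence, ...]:
        return tuple(s for s in self.sequences if s.is_outlier)


def validate_sequence(sequence: StimulusSequence) -> bool:
    """True iff the outlier flag matches the chunk-validity bookkeeping.

    Non-outlier sequences must have all 12 chunks valid; outliers exactly two
    invalid chunks.
    """
    n_invalid = len(sequence.invalid_chunk_indices())
    if sequence.is_outlier:
        return n_invalid == 2
    return n_invalid == 0


def build_vocabulary(seed: int | np.random.Generator = 0) -> Vocabulary:
    """Build the 240-token vocabulary (4 subcategories x 60 tokens).

    The seed only shuffles token order within each subcategory pool; counts
    and identifiers are fixed by design.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tokens: list[WordToken] = []
    for sub in Subcategory:
        ids = [f"{sub.value}_{i:03d}" for i in range(POOL_SIZE)]
        rng.shuffle(ids)
        cat = SUBCATEGORY_CATEGORY[sub]
        tokens.extend(WordToken(word_id=w, category=cat, subcategory=sub) for w in ids)
    return Vocabulary(tokens=tuple(tokens))


def make_alternating_sequence(condition: Condition) -> StimulusSequence:
    """Pattern-only alternating-order sequence: (NNLL or NLLN) x 6."""
    condition = Condition(condition)
    pattern = ALTERNATING_UNIT[condition] * (WORDS_PER_SEQUENCE // 4)
    return StimulusSequence(
        condition=condition, order_type=OrderType.ALTERNATING, categories=pattern
    )


def make_random_sequence(
    condition: Condition, rng: np.random.Generator
) -> StimulusSequence:
    """Pattern-only random-order sequence: 12 i.i.d. draws of the two valid chunks."""
    condition = Condition(condition)
    choices = VALID_CHUNKS[condition]
    picks = rng.integers(0, 2, size=CHUNKS_PER_SEQUENCE)
    pattern = "".join(choices[p] for p in picks)
    return StimulusSequence(
        condition=condition, order_type=OrderType.RANDOM, categories=pattern
    )


def fill_words(
    sequence: StimulusSequence,
    vocabulary: Vocabulary,
    rng: np.random.Generator,
) -> StimulusSequence:
    """Fill a category pattern with concrete tokens.

    One living and one nonliving subcategory are chosen per sequence; each
    slot is filled from the chosen 60-word pool without repetition.
    """
    living_sub = LIVING_SUBCATEGORIES[rng.integers(0, 2)]
    nonliving_sub = NONLIVING_SUBCATEGORIES[rng.integers(0, 2)]
    pools = {
        Category.LIVING: list(vocabulary.by_subcategory(living_sub)),
        Category.NONLIVING: list(vocabulary.by_subcategory(nonliving_sub)),
    }
    counts = {c: sequence.categories.count(c.value) for c in Category}
    draws: dict[Category, list[WordToken]] = {}
    for cat, n_needed in counts.items():
        pool = pools[cat]
        if n_needed > len(pool):
            # Unreachable for the 24-slot / 60-word design; defensive.
            raise ValueError(
                f"pool exhausted: need {n_needed} {cat.value} words, have {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n_needed, replace=False)
        draws[cat] = [pool[i] for i in idx]
    iters = {c: iter(words) for c, words in draws.items()}
    filled = tuple(next(iters[Category(ch)]) for ch in sequence.categories)
    return replace(sequence, words=filled)


def make_outlier(
    sequence: StimulusSequence, rng: np.random.Generator
) -> StimulusSequence:
    """Swap one living and one nonliving word across two distinct chunks.

    The swap position pair is uniform over all eligible (L-position,
    N-position) pairs lying in different chunks; exactly the two touched
    chunks become invalid for the sequence's condition.
    """
    if sequence.is_outlier:
        raise ValueError("sequence is already an outlier")
    cats = list(sequence.categories)
    l_pos = [i for i, c in enumerate(cats) if c == "L"]
    n_pos = [i for i, c in enumerate(cats) if c == "N"]
    pairs = [(i, j) for i in l_pos for j in n_pos if i // 2 != j // 2]
    if not pairs:
        raise ValueError("no eligible swap positions")
    i, j = pairs[rng.integers(0, len(pairs))]
    cats[i], cats[j] = cats[j], cats[i]
    words = sequence.words
    if words is not None:
        w = list(words)
        w[i], w[j] = w[j], w[i]
        words = tuple(w)
    out = replace(sequence, categories="".join(cats), words=words, is_outlier=True)
    if len(out.invalid_chunk_indices()) != 2:  # pragma: no cover - design guarantee
        raise AssertionError("outlier swap did not invalidate exactly two chunks")
    return out


def build_condition_block(
    condition: Condition,
    vocabulary: Vocabulary,
    rng: np.random.Generator,
) -> ConditionBlock:
    """Build one block: 30 alternating + 30 random sequences, 8 + 8 outliers.

    RNG consumption order (fixed for reproducibility): word fills for the 30
    alternating sequences, then pattern+fill for the 30 random sequences,
    then the outlier index draws (alternating first), the outlier swaps, and
    finally the presentation shuffle.
    """
    condition = Condition(condition)
    sequences: list[StimulusSequence] = []
    for _ in range(SEQUENCES_PER_ORDER):
        sequences.append(fill_words(make_alternating_sequence(condition), vocabulary, rng))
    for _ in range(SEQUENCES_PER_ORDER):
        sequences.append(fill_words(make_random_sequence(condition, rng), vocabulary, rng))
    alt_out = rng.choice(SEQUENCES_PER_ORDER, size=OUTLIERS_PER_ORDER, replace=False)
    rnd_out = rng.choice(SEQUENCES_PER_ORDER, size=OUTLIERS_PER_ORDER, replace=False)
    for k in alt_out:
        sequences[k] = make_outlier(sequences[k], rng)
    for k in rnd_out:
        sequences[SEQUENCES_PER_ORDER + k] = make_outlier(
            sequences[SEQUENCES_PER_ORDER + k], rng
        )
    order = tuple(int(i) for i in rng.permutation(len(sequences)))
    return ConditionBlock(
        condition=condition, sequences=tuple(sequences), presentation_order=order
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def sequence_to_record(sequence: StimulusSequence) -> dict:
    return {
        "condition": sequence.condition.value,
        "order_type": sequence.order_type.value,
        "is_outlier": sequence.is_outlier,
        "categories": sequence.categories,
        "word_ids": list(sequence.word_ids) if sequence.word_ids else None,
        "onsets": [float(t) for t in sequence.word_onsets],
    }


def sequence_from_record(record: dict, vocabulary: Vocabulary | None = None) -> StimulusSequence:
    words = None
    if record.get("word_ids") and vocabulary is not None:
        by_id = {t.word_id: t for t in vocabulary.tokens}
        words = tuple(by_id[w] for w in record["word_ids"])
    return StimulusSequence(
        condition=Condition(record["condition"]),
        order_type=OrderType(record["order_type"]),
        categories=record["categories"],
        words=words,
        is_outlier=bool(record["is_outlier"]),
    )


def sequences_to_json(sequences: Iterable[StimulusSequence]) -> str:
    return json.dumps([sequence_to_record(s) for s in sequences], indent=1)


def sequences_from_json(
    text: str, vocabulary: Vocabulary | None = None
) -> list[StimulusSequence]:
    return [sequence_from_record(r, vocabulary) for r in json.loads(text)]


def event_table(sequences: Sequence[StimulusSequence]) -> pd.DataFrame:
    """Long-format event table: one row per word onset."""
    rows = []
    for s_idx, seq in enumerate(sequences):
        ids = seq.word_ids or [None] * WORDS_PER_SEQUENCE
        for w_idx, (onset, cat, wid) in enumerate(
            zip(seq.word_onsets, seq.categories, ids)
        ):
            rows.append(
                {
                    "sequence_index": s_idx,
                    "onset_s": float(onset),
                    "word_id": wid,
                    "category": cat,
                    "chunk_index": w_idx // WORDS_PER_CHUNK,
                    "chunk_onset": w_idx % WORDS_PER_CHUNK == 0,
                }
            )
    return pd.DataFrame(rows)
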