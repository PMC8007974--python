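"""Speech-stream composition and transitional-probability bookkeeping.

The exposure stream concatenates the four words of a pseudo-language in a
pseudo-random order under two restrictions: no word occurs twice in a row,
and every word is followed by each of the other three words as equally often
as the arithmetic allows.  With ``T`` word-to-word transitions distributed
over the 12 ordered pairs, exact equality is impossible when ``12 ∤ T``
(T = 39 for 40-word streams, T = 95 for 96-word streams), so "equally often"
is implemented as maximal balance: every ordered-pair count is ``⌊T/12⌋`` or
``⌈T/12⌉``.

The resulting syllable stream has within-word transitional probabilities of
exactly 1.0 (each syllable appears in a single word at a single position) and
between-word transitional probabilities near 1/3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .lexicon import PseudoLanguage, Syllable

__all__ = [
    "Position",
    "WordOrder",
    "SyllableToken",
    "TransitionStats",
    "generate_word_order",
    "build_stream",
    "transition_stats",
    "within_word_tps",
    "between_word_tps",
    "enumerate_valid_orders",
]


class Position(Enum):
    INITIAL = "initial"
    MEDIAL = "medial"
    FINAL = "final"


_POSITIONS = (Position.INITIAL, Position.MEDIAL, Position.FINAL)


@dataclass(frozen=True)
class WordOrder:
    """A no-immediate-repeat, pair-balanced sequence of word indices."""

    sequence: tuple[int, ...]
    n_repeats: int

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_counts(self) -> Counter:
        """Counts of the realized ordered word pairs."""
        return Counter(zip(self.sequence[:-1], self.sequence[1:]))


@dataclass(frozen=True)
class SyllableToken:
    syllable: Syllable
    word_index: int
    position: Position
    stream_index: int


@dataclass
class TransitionStats:
    """Bigram counts and conditional probabilities over stream syllables."""

    bigram_counts: dict[tuple[Syllable, Syllable], int]
    tp: dict[tuple[Syllable, Syllable], float]


class OrderGenerationError(RuntimeError):
    """The no-repeat / pair-balance constraints could not be satisfied."""


def _attempt_order(n_words: int, n_repeats: int, rng: np.random.Generator) -> tuple[int, ...] | None:
    """One randomized greedy pass: pick the next word among non-repeating
    candidates with remaining uses, preferring the least-used ordered pair."""
    remaining = [n_repeats] * n_words
    pair_count: Counter = Counter()
    first = int(rng.integers(n_words))
    sequence = [first]
    remaining[first] -= 1
    for _ in range(n_words * n_repeats - 1):
        cur = sequence[-1]
        candidates = [w for w in range(n_words) if w != cur and remaining[w] > 0]
        if not candidates:
            return None
        counts = np.array([pair_count[(cur, w)] for w in candidates])
        best = [w for w, c in zip(candidates, counts) if c == counts.min()]
        nxt = best[int(rng.integers(len(best)))]
        sequence.append(nxt)
        remaining[nxt] -= 1
        pair_count[(cur, nxt)] += 1
    return tuple(sequence)


def _is_balanced(sequence: tuple[int, ...], n_words: int) -> bool:
    pairs = Counter(zip(sequence[:-1], sequence[1:]))
    counts = [pairs[(a, b)] for a in range(n_words) for b in range(n_words) if a != b]
    return max(counts) - min(counts) <= 1


def generate_word_order(
    n_repeats: int,
    n_words: int = 4,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1_000,
) -> WordOrder:
    """Generate a pseudo-random word order under the stream constraints.

    Greedy passes are restarted until one satisfies both the exact per-word
    repeat counts and the pair-balance invariant (max - min pair count <= 1).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if n_words < 2 and n_repeats > 1:
        raise OrderGenerationError("no-repeat constraint unsatisfiable for n_words < 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        sequence = _attempt_order(n_words, n_repeats, rng)
        if sequence is not None and _is_balanced(sequence, n_words):
            return WordOrder(sequence=sequence, n_repeats=n_repeats)
    raise OrderGenerationError(
        f"no balanced order found in {max_attempts} attempts "
        f"(n_words={n_words}, n_repeats={n_repeats})"
    )


def build_stream(language: PseudoLanguage, order: WordOrder) -> list[SyllableToken]:
    """Expand a word order into the ordered syllable-token stream."""
    if any(i >= len(language.words) for i in order.sequence):
        raise ValueError("word index out of range for language")
    tokens: list[SyllableToken] = []
    for word_index in order.sequence:
        for pos, syll in zip(_POSITIONS, language.words[word_index].syllables):
            tokens.append(
                SyllableToken(
                    syllable=syll,
                    word_index=word_index,
                    position=pos,
                    stream_index=len(tokens),
                )
            )
    return tokens


def transition_stats(tokens: list[SyllableToken]) -> TransitionStats:
    """Bigram counts and forward transitional probabilities P(next | current).

    The stream-final syllable contributes no outgoing transition; denominators
    count antecedent occurrences that have a successor.
    """
    if len(tokens) < 2:
        raise ValueError("need at least 2 tokens to compute transitions")
    bigrams: Counter = Counter(
        (a.syllable, b.syllable) for a, b in zip(tokens[:-1], tokens[1:])
    )
    antecedent: Counter = Counter(t.syllable for t in tokens[:-1])
    tp = {pair: count / antecedent[pair[0]] for pair, count in bigrams.items()}
    return TransitionStats(bigram_counts=dict(bigrams), tp=tp)


def within_word_tps(tokens: list[SyllableToken], stats: TransitionStats | None = None) -> list[float]:
    """TPs of every realized initial→medial and medial→final bigram."""
    stats = stats or transition_stats(tokens)
    values = []
    for a, b in zip(tokens[:-1], tokens[1:]):
        if a.position is not Position.FINAL:
            values.append(stats.tp[(a.syllable, b.syllable)])
    return values


def between_word_tps(tokens: list[SyllableToken], stats: TransitionStats | None = None) -> list[float]:
    """TPs of every realized word-final → word-initial bigram (distinct pairs)."""
    stats = stats or transition_stats(tokens)
    pairs = {
        (a.syllable, b.syllable)
        for a, b in zip(tokens[:-1], tokens[1:])
        if a.position is Position.FINAL
    }
    return [stats.tp[p] for p in sorted(pairs, key=str)]


def enumerate_valid_orders(n_words: int, n_repeats: int) -> list[tuple[int, ...]]:
    """Brute-force enumeration of all sequences satisfying the order
    constraints; exponential, intended for tiny problems only."""
    from itertools import permutations as _perms

    base = [w for w in range(n_words) for _ in range(n_repeats)]
    valid = set()
    for perm in set(_perms(base)):
        if all(a != b for a, b in zip(perm[:-1], perm[1:])) and _is_balanced(perm, n_words):
            valid.add(perm)
    return sorted(valid)
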