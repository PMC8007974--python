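"""Test-item construction: statistical words and boundary-spanning part-words.

For a 4-word language there are 12 ordered word pairs (A, B), A != B, and
each pair yields one part-word per class:

* **part-words 1-2**: final syllable of A + initial and medial syllables of
  B (the cue-carrying final syllable lands word-initially);
* **part-words 2-1**: medial and final syllables of A + initial syllable of
  B (the cue-carrying final syllable lands word-medially).

A test set holds 12 items: the 4 words plus 4 part-words of each class.  The
within-subjects experiments select part-words per participant and condition
so that every word contributes its "first part" exactly once and its "second
part" exactly once per class — formally, the word-pairing is a derangement of
the four word indices, of which there are exactly 9.  The between-subjects
pilot used one fixed, hand-picked item list for Language 0 (which does *not*
obey the derangement constraint: /toga/ serves as a second part twice).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .lexicon import PseudoLanguage, Syllable, TABLE1_LANGUAGES

__all__ = [
    "TestItem",
    "TestSet",
    "STIMULUS_TYPES",
    "enumerate_part_words",
    "derangements",
    "select_test_set",
]

STIMULUS_TYPES = ("WORD", "PW12", "PW21")

#: Fixed part-word selections of the between-subjects pilot (Language 0),
#: written as (source word A index, source word B index) per class.
_EXP1_FIXED_PW12 = [(3, 1), (0, 2), (2, 1), (1, 3)]  # ku-toga ki-puni do-toga bi-dapi
_EXP1_FIXED_PW21 = [(0, 2), (3, 0), (0, 3), (2, 0)]  # tuki-pu piku-ba tuki-da nido-ba


@dataclass(frozen=True)
class TestItem:
    syllables: tuple[Syllable, Syllable, Syllable]
    stimulus_type: str  # WORD | PW12 | PW21
    source_words: tuple[int, ...]  # (A,) for words, (A, B) for part-words

    def __str__(self) -> str:
        return "".join(str(s) for s in self.syllables)


@dataclass(frozen=True)
class TestSet:
    items: tuple[TestItem, ...]
    language_id: str
    selection_seed: int | None = None

    def by_type(self, stimulus_type: str) -> list[TestItem]:
        return [i for i in self.items if i.stimulus_type == stimulus_type]


def _make_part_word(language: PseudoLanguage, a: int, b: int, pw_class: str) -> TestItem:
    wa, wb = language.words[a].syllables, language.words[b].syllables
    if pw_class == "PW12":
        sylls = (wa[2], wb[0], wb[1])
    elif pw_class == "PW21":
        sylls = (wa[1], wa[2], wb[0])
    else:
        raise ValueError(f"unknown part-word class {pw_class!r}")
    return TestItem(syllables=sylls, stimulus_type=pw_class, source_words=(a, b))


def enumerate_part_words(language: PseudoLanguage, part_word_class: str) -> list[TestItem]:
    """All n(n-1) = 12 part-words of one class, over ordered word pairs."""
    return [
        _make_part_word(language, a, b, part_word_class)
        for a in range(4)
        for b in range(4)
        if a != b
    ]


def derangements(n: int = 4) -> list[tuple[int, ...]]:
    """All permutations of range(n) with no fixed point (9 for n = 4)."""
    return [p for p in permutations(range(n)) if all(p[i] != i for i in range(n))]


def _word_items(language: PseudoLanguage) -> list[TestItem]:
    return [
        TestItem(syllables=w.syllables, stimulus_type="WORD", source_words=(i,))
        for i, w in enumerate(language.words)
    ]


def select_test_set(
    language: PseudoLanguage,
    mode: str,
    seed: int | np.random.Generator | None = None,
) -> TestSet:
    """Select the 12 test items (4 WORD + 4 PW12 + 4 PW21).

    ``mode="FIXED_EXP1"`` returns the pilot's hand-picked list and is only
    valid for Language 0.  ``mode="RANDOM_EXP2"`` draws, per part-word class,
    a uniform derangement sigma and pairs word i's part with word sigma(i)'s
    part, so each first and second part is represented exactly once.
    """
    if mode == "FIXED_EXP1":
        if language.word_strings() != TABLE1_LANGUAGES[0].word_strings():
            raise ValueError("FIXED_EXP1 selection is defined for Language 0 only")
        items = _word_items(language)
        items += [_make_part_word(language, a, b, "PW12") for a, b in _EXP1_FIXED_PW12]
        items += [_make_part_word(language, a, b, "PW21") for a, b in _EXP1_FIXED_PW21]
        return TestSet(items=tuple(items), language_id=language.language_id)
    if mode != "RANDOM_EXP2":
        raise ValueError(f"unknown selection mode {mode!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_sigma = derangements(4)
    items = _word_items(language)
    for pw_class in ("PW12", "PW21"):
        sigma = all_sigma[int(rng.integers(len(all_sigma)))]
        items += [_make_part_word(language, a, sigma[a], pw_class) for a in range(4)]
    return TestSet(
        items=tuple(items),
        language_id=language.language_id,
        selection_seed=None if isinstance(seed, np.random.Generator) else seed,
    )
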