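"""Pseudo-language generation and validation.

A pseudo-language is a set of four trisyllabic CV nonsense words drawn from a
fixed consonant/vowel pool.  Two constraint profiles are supported:

``EXP1``
    4 vowels (a, u, i, o) x 7 consonants (p, t, k, b, d, g, n); within a word
    no syllable may repeat.

``EXP2``
    5 vowels (a, e, i, o, u) x 13 consonants (stops b d g p t k, fricatives
    f v s, sonorants m n l r); within a word no vowel repeats, within a
    language every consonant (and hence every syllable) is unique, and the
    12 vowel slots are filled so that two vowels occur three times and three
    vowels occur twice.  Sets of four such languages additionally require
    that no syllable occurs in more than two languages.

Generation is rejection sampling over uniformly drawn candidate words, which
terminates quickly because the constraint sets are loose relative to the pool
sizes, and carries no ordering bias.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Syllable",
    "WordForm",
    "LanguageProfile",
    "PseudoLanguage",
    "ValidationReport",
    "EXP1",
    "EXP2",
    "TABLE1_LANGUAGES",
    "generate_language",
    "generate_language_set",
    "validate_language",
    "validate_language_set",
    "language_set_manifest",
]


@dataclass(frozen=True, order=True)
class Syllable:
    """A single CV syllable."""

    consonant: str
    vowel: str

    def __post_init__(self) -> None:
        if len(self.consonant) != 1 or len(self.vowel) != 1:
            raise ValueError("syllable symbols must be single characters")

    def __str__(self) -> str:
        return self.consonant + self.vowel


@dataclass(frozen=True)
class WordForm:
    """An ordered triple of syllables."""

    syllables: tuple[Syllable, Syllable, Syllable]

    def __post_init__(self) -> None:
        if len(self.syllables) != 3:
            raise ValueError("a word has exactly 3 syllables")

    @classmethod
    def from_string(cls, text: str) -> "WordForm":
        """Parse a six-character CV-CV-CV string such as ``'batuki'``."""
        text = text.strip("/")
        if len(text) != 6:
            raise ValueError(f"cannot parse {text!r} as three CV syllables")
        sylls = tuple(Syllable(text[i], text[i + 1]) for i in (0, 2, 4))
        return cls(sylls)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(str(s) for s in self.syllables)


@dataclass(frozen=True)
class LanguageProfile:
    """Symbol pools plus the named constraint set they feed."""

    name: str  # "EXP1" | "EXP2"
    vowel_pool: frozenset[str]
    consonant_pool: frozenset[str]


EXP1 = LanguageProfile(
    name="EXP1",
    vowel_pool=frozenset("auio"),
    consonant_pool=frozenset("ptkbdgn"),
)

EXP2 = LanguageProfile(
    name="EXP2",
    vowel_pool=frozenset("aeiou"),
    consonant_pool=frozenset("bdgptk" "fvs" "mnlr"),
)


@dataclass(frozen=True)
class PseudoLanguage:
    """Four trisyllabic words plus the profile they satisfy."""

    words: tuple[WordForm, WordForm, WordForm, WordForm]
    profile: LanguageProfile
    language_id: str = "language"

    def __post_init__(self) -> None:
        if len(self.words) != 4:
            raise ValueError("a pseudo-language has exactly 4 words")

    @classmethod
    def from_strings(
        cls, words: Sequence[str], profile: LanguageProfile, language_id: str = "language"
    ) -> "PseudoLanguage":
        forms = tuple(WordForm.from_string(w) for w in words)
        return cls(forms, profile, language_id)  # type: ignore[arg-type]

    @property
    def syllables(self) -> list[Syllable]:
        """All 12 syllables, word by word."""
        return [s for w in self.words for s in w.syllables]

    def word_strings(self) -> list[str]:
        return [str(w) for w in self.words]


#: The printed languages: Language 0 drives the between-subjects design, languages
#: 1-4 the two within-subjects designs.
TABLE1_LANGUAGES: dict[int, PseudoLanguage] = {
    0: PseudoLanguage.from_strings(["batuki", "togabi", "punido", "dapiku"], EXP1, "language0"),
    1: PseudoLanguage.from_strings(["bakupo", "delaru", "fumesi", "gonite"], EXP2, "language1"),
    2: PseudoLanguage.from_strings(["pifoke", "rovali", "nusema", "tabigu"], EXP2, "language2"),
    3: PseudoLanguage.from_strings(["dafego", "pebomi", "kirune", "lutiva"], EXP2, "language3"),
    4: PseudoLanguage.from_strings(["mabopi", "veduka", "sigale", "tonifu"], EXP2, "language4"),
}


@dataclass
class ValidationReport:
    """Outcome of constraint checking; never raised, always returned."""

    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _check_pools(language: PseudoLanguage, violations: list[str]) -> None:
    for syll in language.syllables:
        if syll.consonant not in language.profile.consonant_pool:
            violations.append(f"consonant '{syll.consonant}' outside pool")
        if syll.vowel not in language.profile.vowel_pool:
            violations.append(f"vowel '{syll.vowel}' outside pool")


def validate_language(language: PseudoLanguage) -> ValidationReport:
    """Check every profile constraint; report violations by name."""
    violations: list[str] = []
    _check_pools(language, violations)

    if language.profile.name == "EXP1":
        for word in language.words:
            if len(set(word.syllables)) != 3:
                violations.append(f"identical syllables within word /{word}/")
    elif language.profile.name == "EXP2":
        for word in language.words:
            vowels = [s.vowel for s in word.syllables]
            if len(set(vowels)) != 3:
                violations.append(f"repeated vowel within word /{word}/")
        consonants = [s.consonant for s in language.syllables]
        if len(set(consonants)) != 12:
            violations.append("consonant used more than once in language")
        if len(set(language.syllables)) != 12:
            violations.append("syllable not unique within language")
        vowel_counts = sorted(Counter(s.vowel for s in language.syllables).values())
        if vowel_counts != [2, 2, 2, 3, 3]:
            violations.append("vowel counts are not {3,3,2,2,2} over five vowels")
    else:  # pragma: no cover - unknown profile
        violations.append(f"unknown profile {language.profile.name!r}")

    return ValidationReport(passed=not violations, violations=violations)


def validate_language_set(languages: Sequence[PseudoLanguage]) -> ValidationReport:
    """Each language valid individually, and no syllable in more than two languages."""
    violations: list[str] = []
    for lang in languages:
        rep = validate_language(lang)
        if not rep:
            violations.extend(f"{lang.language_id}: {v}" for v in rep.violations)
    tally: Counter[Syllable] = Counter()
    for lang in languages:
        tally.update(set(lang.syllables))  # per-language syllables are unique already
    for syll, count in tally.items():
        if count > 2:
            violations.append(f"syllable /{syll}/ occurs in {count} languages")
    return ValidationReport(passed=not violations, violations=violations)


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its retry budget."""


def _draw_word(rng: np.random.Generator, profile: LanguageProfile) -> WordForm:
    cons = sorted(profile.consonant_pool)
    vows = sorted(profile.vowel_pool)
    sylls = tuple(
        Syllable(cons[rng.integers(len(cons))], vows[rng.integers(len(vows))])
        for _ in range(3)
    )
    return WordForm(sylls)  # type: ignore[arg-type]


def _word_acceptable(
    word: WordForm,
    profile: LanguageProfile,
    accepted: list[WordForm],
    blocked: set[str],
) -> bool:
    """Word-level rejection test against the constraints accumulated so far."""
    if str(word) in blocked or any(str(word) == str(w) for w in accepted):
        return False
    if profile.name == "EXP1":
        return len(set(word.syllables)) == 3
    # EXP2: vowels distinct within the word, no consonant reused anywhere,
    # and no vowel pushed past three occurrences.
    if len({s.vowel for s in word.syllables}) != 3:
        return False
    used_cons = {s.consonant for w in accepted for s in w.syllables}
    cons = [s.consonant for s in word.syllables]
    if len(set(cons)) != 3 or used_cons & set(cons):
        return False
    vowel_count = Counter(s.vowel for w in accepted for s in w.syllables)
    vowel_count.update(s.vowel for s in word.syllables)
    counts = [vowel_count[v] for v in sorted(profile.vowel_pool)]
    return _vowels_completable(counts, words_left=3 - len(accepted))


def _vowels_completable(counts: Sequence[int], words_left: int) -> bool:
    """Can per-vowel ``counts`` still be extended to the {3,3,2,2,2} target by
    ``words_left`` further words of three *distinct* vowels each?

    Checks every distinct assignment of the target multiset to the five
    vowels: all deficits non-negative and no single deficit larger than the
    number of remaining words (a word contributes at most one token of any
    vowel).
    """
    from itertools import permutations as _perms

    for target in set(_perms((3, 3, 2, 2, 2))):
        deficits = [t - c for t, c in zip(target, counts)]
        if all(d >= 0 for d in deficits) and max(deficits) <= words_left:
            return True
    return False


def generate_language(
    profile: LanguageProfile,
    seed: int | np.random.Generator,
    blocklist: Iterable[str] | None = None,
    language_id: str = "language",
    max_tries: int = 10_000,
) -> PseudoLanguage:
    """Rejection-sample a valid pseudo-language.

    Candidate words are drawn uniformly from the profile pools and accepted or
    rejected one at a time against the constraints accumulated so far; a
    completed 4-word draw that fails whole-language validation (e.g. the EXP2
    vowel multiset) is discarded and the language is redrawn.  ``blocklist``
    is an optional set of word strings (e.g. real German/English words a
    caller wants to exclude); no lexicon is bundled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocked = set(blocklist or ())
    draws = 0
    while draws < max_tries:
        accepted: list[WordForm] = []
        stalled = 0
        while len(accepted) < 4 and draws < max_tries and stalled < 2_000:
            word = _draw_word(rng, profile)
            draws += 1
            if _word_acceptable(word, profile, accepted, blocked):
                accepted.append(word)
                stalled = 0
            else:
                stalled += 1
        if len(accepted) < 4:
            continue
        candidate = PseudoLanguage(tuple(accepted), profile, language_id)  # type: ignore[arg-type]
        if validate_language(candidate):
            return candidate
    raise GenerationError(f"no valid language found in {max_tries} word draws")


def generate_language_set(
    profile: LanguageProfile,
    n_languages: int,
    seed: int,
    max_tries: int = 10_000,
) -> list[PseudoLanguage]:
    """Generate mutually constrained languages (no syllable in more than two)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        languages = [
            generate_language(profile, rng, language_id=f"language{i + 1}", max_tries=max_tries)
            for i in range(n_languages)
        ]
        if validate_language_set(languages):
            return languages
    raise GenerationError(f"no valid language set found in {max_tries} tries")


def language_set_manifest(
    languages: Sequence[PseudoLanguage], seed: int | None = None
) -> str:
    """JSON manifest (language_id, words, profile, seed) for a language set."""
    payload = {
        "seed": seed,
        "languages": [
            {
                "language_id": lang.language_id,
                "profile": lang.profile.name,
                "words": lang.word_strings(),
            }
            for lang in languages
        ],
    }
    return json.dumps(payload, indent=2)
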