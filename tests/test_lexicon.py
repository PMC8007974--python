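"""Pseudo-language generation and constraint validation."""

from collections import Counter

import numpy as np
import pytest

from seglab import lexicon
from seglab.lexicon import (
    EXP1,
    EXP2,
    GenerationError,
    PseudoLanguage,
    TABLE1_LANGUAGES,
    generate_language,
    generate_language_set,
    validate_language,
    validate_language_set,
)


def test_profile_pools():
    assert EXP1.vowel_pool == frozenset("auio")
    assert EXP1.consonant_pool == frozenset("ptkbdgn")
    assert EXP2.vowel_pool == frozenset("aeiou")
    assert len(EXP2.consonant_pool) == 13
    assert frozenset("bdgptk") <= EXP2.consonant_pool  # stops
    assert frozenset("fvs") <= EXP2.consonant_pool  # fricatives
    assert frozenset("mnlr") <= EXP2.consonant_pool  # sonorants


@pytest.mark.parametrize("index", range(5))
def test_printed_languages_validate(index):
    """All five printed languages pass their profile's validator."""
    report = validate_language(TABLE1_LANGUAGES[index])
    assert report.passed, report.violations


def test_printed_language_set_cross_constraint():
    """Across printed languages 1-4 no syllable occurs more than twice."""
    langs = [TABLE1_LANGUAGES[i] for i in (1, 2, 3, 4)]
    assert validate_language_set(langs).passed
    tally = Counter(s for lang in langs for s in set(lang.syllables))
    assert max(tally.values()) <= 2


def test_exp1_repeated_syllable_fails():
    bad = PseudoLanguage.from_strings(["baba" + "ki", "togabi", "punido", "dapiku"], EXP1)
    report = validate_language(bad)
    assert not report.passed
    assert any("identical syllables" in v for v in report.violations)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_generated_exp2_language_structure(seed):
    """Generated languages use 12 distinct consonants and the 3/3/2/2/2 vowel split."""
    lang = generate_language(EXP2, seed=seed)
    consonants = [s.consonant for s in lang.syllables]
    assert len(consonants) == 12 and len(set(consonants)) == 12
    vowel_counts = sorted(Counter(s.vowel for s in lang.syllables).values())
    assert vowel_counts == [2, 2, 2, 3, 3]
    assert validate_language(lang).passed


def test_generation_reproducible():
    a = generate_language(EXP2, seed=99)
    b = generate_language(EXP2, seed=99)
    assert a.word_strings() == b.word_strings()
    assert generate_language(EXP1, seed=7).word_strings() == generate_language(
        EXP1, seed=7
    ).word_strings()


def test_blocklist_exhaustive_fails():
    """Blocking every CV^3 word over the EXP1 pool makes generation impossible."""
    all_words = {
        f"{c1}{v1}{c2}{v2}{c3}{v3}"
        for c1 in EXP1.consonant_pool
        for v1 in EXP1.vowel_pool
        for c2 in EXP1.consonant_pool
        for v2 in EXP1.vowel_pool
        for c3 in EXP1.consonant_pool
        for v3 in EXP1.vowel_pool
    }
    with pytest.raises(GenerationError):
        generate_language(EXP1, seed=0, blocklist=all_words, max_tries=3_000)


def test_language_set_cross_constraint_holds():
    """Exhaustive tally over all 48 syllables of a generated 4-language set."""
    langs = generate_language_set(EXP2, 4, seed=5)
    assert len(langs) == 4
    tally = Counter(s for lang in langs for s in lang.syllables)
    assert max(tally.values()) <= 2
    assert validate_language_set(langs).passed


def test_single_language_set_reduces_to_generate():
    (lang,) = generate_language_set(EXP2, 1, seed=8)
    assert validate_language(lang).passed


def _brute_force_valid(lang: PseudoLanguage) -> bool:
    """Independent re-implementation of every profile constraint."""
    sylls = [str(s) for w in lang.words for s in w.syllables]
    if lang.profile.name == "EXP1":
        for w in lang.words:
            ss = [str(s) for s in w.syllables]
            if ss[0] == ss[1] or ss[1] == ss[2] or ss[0] == ss[2]:
                return False
        pool_ok = all(s[0] in "ptkbdgn" and s[1] in "auio" for s in sylls)
        return pool_ok
    # EXP2
    if any(s[0] not in "bdgptkfvsmnlr" or s[1] not in "aeiou" for s in sylls):
        return False
    for w in lang.words:
        vv = [s.vowel for s in w.syllables]
        if len(set(vv)) != 3:
            return False
    cons = [s[0] for s in sylls]
    if sorted(Counter(cons).values()) != [1] * 12:
        return False
    if len(set(sylls)) != 12:
        return False
    return sorted(Counter(s[1] for s in sylls).values()) == [2, 2, 2, 3, 3]


def test_validator_agrees_with_brute_force_oracle():
    """Validator and an independent checker agree on 100 valid/corrupted languages."""
    rng = np.random.default_rng(42)
    for i in range(100):
        profile = EXP2 if i % 2 == 0 else EXP1
        lang = generate_language(profile, seed=rng)
        if i % 3 == 0:  # corrupt: overwrite one word with a copy of another
            words = list(lang.words)
            words[1] = words[0]
            lang = PseudoLanguage(tuple(words), profile, lang.language_id)
        assert validate_language(lang).passed == _brute_force_valid(lang)


def test_manifest_round_trip():
    import json

    langs = generate_language_set(EXP2, 4, seed=6)
    manifest = json.loads(lexicon.language_set_manifest(langs, seed=6))
    assert manifest["seed"] == 6
    assert [m["words"] for m in manifest["languages"]] == [l.word_strings() for l in langs]
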