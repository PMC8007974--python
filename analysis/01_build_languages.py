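"""Validate the printed pseudo-languages and generate a fresh constrained set.

Checks that the five printed languages (one for the between-subjects pilot,
four mutually constrained ones for the within-subjects designs) satisfy their
constraint profiles, then generates a fresh 4-language set from the same
pools and writes both to results/.
"""

import json
from pathlib import Path

from seglab import lexicon

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

print("Printed pseudo-languages:")
for idx, lang in lexicon.TABLE1_LANGUAGES.items():
    report = lexicon.validate_language(lang)
    print(f"  language {idx} ({lang.profile.name}): {lang.word_strings()} -> "
          f"{'valid' if report else report.violations}")

set_report = lexicon.validate_language_set(
    [lexicon.TABLE1_LANGUAGES[i] for i in (1, 2, 3, 4)]
)
print(f"Cross-language constraint on printed languages 1-4 "
      f"(no syllable in more than two languages): {'holds' if set_report else set_report.violations}")

seed = 2021
fresh = lexicon.generate_language_set(lexicon.EXP2, n_languages=4, seed=seed)
print(f"\nFresh 4-language set (seed {seed}):")
for lang in fresh:
    print(f"  {lang.language_id}: {lang.word_strings()}")
assert lexicon.validate_language_set(fresh)

out = RESULTS / "languages.json"
out.write_text(lexicon.language_set_manifest(fresh, seed=seed))
print(f"\nWrote {out}")
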