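"""Enumerate part-words and build per-participant test sets.

Reproduces the full part-word inventory of printed Language 1 (12 items per
class), the fixed test set of the between-subjects pilot, and example
constraint-respecting random selections for the within-subjects designs.
"""

from pathlib import Path

import pandas as pd

from seglab import items, lexicon

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

lang1 = lexicon.TABLE1_LANGUAGES[1]
rows = []
for pw_class in ("PW12", "PW21"):
    for item in items.enumerate_part_words(lang1, pw_class):
        rows.append({
            "class": pw_class,
            "part_word": str(item),
            "source_word_a": str(lang1.words[item.source_words[0]]),
            "source_word_b": str(lang1.words[item.source_words[1]]),
        })
inventory = pd.DataFrame(rows)
inventory.to_csv(RESULTS / "part_words_language1.csv", index=False)
print(f"Language 1 part-word inventory: "
      f"{(inventory['class'] == 'PW12').sum()} of class 1-2, "
      f"{(inventory['class'] == 'PW21').sum()} of class 2-1")

fixed = items.select_test_set(lexicon.TABLE1_LANGUAGES[0], "FIXED_EXP1")
print("\nFixed pilot test set (Language 0):")
for stype in items.STIMULUS_TYPES:
    print(f"  {stype}: {[str(i) for i in fixed.by_type(stype)]}")

print(f"\nValid per-class random selections are derangements of the 4 words: "
      f"{len(items.derangements(4))} possibilities per class.")
for seed in (0, 1):
    ts = items.select_test_set(lang1, "RANDOM_EXP2", seed=seed)
    print(f"  seed {seed}: PW12 {[str(i) for i in ts.by_type('PW12')]}, "
          f"PW21 {[str(i) for i in ts.by_type('PW21')]}")
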