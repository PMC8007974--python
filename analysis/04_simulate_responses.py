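"""Simulate listener judgments for the three experimental designs.

Runs the cue-pattern response model through the between-subjects design
(202 participants x 1 of 6 conditions), the within-subjects design
(34 x 4 conditions), and the 4-of-6 within-subjects design (42 participants),
and exports the long-format response tables for downstream analysis
(including external mixed-model fitting).
"""

from pathlib import Path

from seglab import sdt, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 2021
DESIGNS = {
    "exp1": simulate.EXP1_DESIGN,
    "exp2": simulate.EXP2_DESIGN,
    "exp3": simulate.EXP3_DESIGN,
}

for label, design in DESIGNS.items():
    records = simulate.simulate_responses(design, simulate.CUE_PATTERN, seed=SEED)
    n_correct = sum(r.correct for r in records)
    path = sdt.export_long_format(records, RESULTS / f"responses_{label}.csv")
    print(f"{label}: {design.layout}, {design.n_participants} participants -> "
          f"{len(records)} judgments ({n_correct} correct); wrote {path.name}")
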