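"""Signal-detection analysis of the simulated response tables.

Reads the long-format tables written by 04_simulate_responses.py, computes
per-participant d' values with the 1/(2N) adjustment, per-condition group
means with 95% t-intervals, and bootstrap proportion-correct tables by
condition and stimulus type, and reports which prosodic cues helped or hurt
segmentation in the simulation.
"""

from pathlib import Path

import pandas as pd

from seglab import sdt

RESULTS = Path(__file__).resolve().parent.parent / "results"

for label in ("exp1", "exp2", "exp3"):
    path = RESULTS / f"responses_{label}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 04_simulate_responses.py first")
    df = sdt.import_long_format(path)

    dprimes = sdt.participant_d_primes(df)
    summaries = sdt.group_summary(dprimes)
    table = pd.DataFrame(
        {
            "condition": [g.condition for g in summaries],
            "mean_d_prime": [g.mean_d_prime for g in summaries],
            "ci_low": [g.ci_low for g in summaries],
            "ci_high": [g.ci_high for g in summaries],
            "n": [g.n_participants for g in summaries],
            "excludes_chance": [g.excludes_zero for g in summaries],
        }
    ).round(3)
    table.to_csv(RESULTS / f"dprime_summary_{label}.csv", index=False)

    props = sdt.proportion_correct(df, n_bootstrap=1_000, seed=7).round(3)
    props.to_csv(RESULTS / f"proportions_{label}.csv", index=False)

    print(f"\n=== {label}: group d' (mean, 95% CI) ===")
    print(table.to_string(index=False))
    by_cond = {g.condition: g for g in summaries}
    if "pause" in by_cond and "baseline" in by_cond:
        gap = not by_cond["pause"].overlaps(by_cond["baseline"])
        print(f"pause vs baseline CIs {'do not ' if gap else ''}overlap"
              f"{' -> pauses facilitate segmentation' if gap else ''}")
    if "shortening" in by_cond and by_cond["shortening"].mean_d_prime < 0:
        sh = props[props["condition"] == "shortening"].set_index("stimulus_type")
        worst = sh["mean_correct"].idxmin()
        print(f"shortening mean d' < 0 (cue conflict); worst cell: {worst}")
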