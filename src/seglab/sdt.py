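"""Signal-detection analysis of word/part-word judgments.

Per participant-condition cell (4 signal trials = statistical words, 8 noise
trials = part-words), hits are words accepted as words and false alarms are
part-words accepted as words.  Proportions of 0 and 1 are moved off the
boundary with the standard 1/(2N) rule — N being the trial count of the
respective rate, so 1/8 for hits and 1/16 for false alarms here — and
sensitivity is

    d' = z(adjusted hit rate) - z(adjusted false-alarm rate)

with z the standard-normal quantile.  d' = 0 is chance discrimination;
negative d' means part-words were preferentially accepted.  Group summaries
report per-condition means of participant d' values with t-based 95%
confidence intervals; proportion-correct tables bootstrap over participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import ResponseRecord, records_to_frame

__all__ = [
    "SDTCounts",
    "DPrimeResult",
    "GroupSummary",
    "adjust_rates",
    "d_prime",
    "counts_from_records",
    "participant_d_primes",
    "group_summary",
    "proportion_correct",
    "export_long_format",
    "import_long_format",
]


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class DPrimeResult:
    raw_hit_rate: float
    raw_fa_rate: float
    adj_hit_rate: float
    adj_fa_rate: float
    d_prime: float


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    mean_d_prime: float
    ci_low: float
    ci_high: float
    n_participants: int

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0

    def overlaps(self, other: "GroupSummary") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


def _adjust(rate: float, n: int) -> float:
    """1/(2N) rule: move boundary proportions off 0 and 1, leave the rest."""
    if rate == 0.0:
        return 1 / (2 * n)
    if rate == 1.0:
        return 1 - 1 / (2 * n)
    return rate


def adjust_rates(counts: SDTCounts) -> tuple[float, float]:
    """Boundary-adjusted (hit rate, false-alarm rate)."""
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    hit = _adjust(counts.hits / counts.n_signal, counts.n_signal)
    fa = _adjust(counts.false_alarms / counts.n_noise, counts.n_noise)
    return hit, fa


def d_prime(counts: SDTCounts) -> DPrimeResult:
    """Sensitivity d' = z(adjusted H) - z(adjusted F)."""
    adj_hit, adj_fa = adjust_rates(counts)
    return DPrimeResult(
        raw_hit_rate=counts.hits / counts.n_signal,
        raw_fa_rate=counts.false_alarms / counts.n_noise,
        adj_hit_rate=adj_hit,
        adj_fa_rate=adj_fa,
        d_prime=float(sps.norm.ppf(adj_hit) - sps.norm.ppf(adj_fa)),
    )


def _frame(records: Sequence[ResponseRecord] | pd.DataFrame) -> pd.DataFrame:
    """Accept either raw records or an already long-format table."""
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def counts_from_records(records: Sequence[ResponseRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per participant-condition SDT counts from simulated judgments."""
    df = _frame(records)
    yes = df["response"] == "WORD_YES"
    signal = df["stimulus_type"] == "WORD"
    df = df.assign(
        hits=(yes & signal).astype(int),
        misses=(~yes & signal).astype(int),
        false_alarms=(yes & ~signal).astype(int),
        correct_rejections=(~yes & ~signal).astype(int),
    )
    out = (
        df.groupby(["participant", "condition"], sort=True)[
            ["hits", "misses", "false_alarms", "correct_rejections"]
        ]
        .sum()
        .reset_index()
    )
    return out


def participant_d_primes(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """One row per participant-condition with adjusted rates and d'."""
    table = counts_from_records(records)
    results = [
        d_prime(SDTCounts(r.hits, r.misses, r.false_alarms, r.correct_rejections))
        for r in table.itertuples()
    ]
    table = table.copy()
    table["adj_hit_rate"] = [r.adj_hit_rate for r in results]
    table["adj_fa_rate"] = [r.adj_fa_rate for r in results]
    table["d_prime"] = [r.d_prime for r in results]
    return table


def group_summary(
    d_primes: pd.DataFrame, level: float = 0.95
) -> list[GroupSummary]:
    """Per-condition mean d' with t-based confidence intervals.

    ``d_primes`` is the output of :func:`participant_d_primes` (columns
    ``condition`` and ``d_prime``, one row per participant-condition).
    """
    out = []
    for cond, grp in d_primes.groupby("condition", sort=True):
        values = grp["d_prime"].to_numpy()
        n = len(values)
        if n < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 participants")
        mean = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(n))
        tcrit = float(sps.t.ppf(0.5 + level / 2, df=n - 1))
        out.append(
            GroupSummary(
                condition=str(cond),
                mean_d_prime=mean,
                ci_low=mean - tcrit * se,
                ci_high=mean + tcrit * se,
                n_participants=n,
            )
        )
    return out


def proportion_correct(
    records: Sequence[ResponseRecord],
    n_bootstrap: int = 1_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean proportion correct per condition x stimulus type, with a
    participant-resampling bootstrap CI.  Chance reference is 0.5."""
    if not len(records):
        raise ValueError("empty record list")
    rng = np.random.default_rng(seed)
    df = _frame(records)
    per_part = (
        df.groupby(["condition", "stimulus_type", "participant"], sort=True)["correct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (cond, stype), cell in per_part.groupby(["condition", "stimulus_type"], sort=True):
        values = cell["correct"].to_numpy()
        boots = np.array(
            [
                values[rng.integers(len(values), size=len(values))].mean()
                for _ in range(n_bootstrap)
            ]
        )
        lo, hi = np.quantile(boots, [(1 - level) / 2, 0.5 + level / 2])
        rows.append(
            {
                "condition": cond,
                "stimulus_type": stype,
                "mean_correct": float(values.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_participants": len(values),
            }
        )
    return pd.DataFrame(rows)


def export_long_format(records: Sequence[ResponseRecord], path: str | Path) -> Path:
    """Write the long-format response table (one row per judgment) as CSV,
    ready for external mixed-model fitting."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def import_long_format(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`export_long_format`."""
    return pd.read_csv(path, dtype={"correct": bool})
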