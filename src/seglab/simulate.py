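"""Synthetic listeners: Bernoulli word/part-word judgments under a logistic
response model.

Each simulated participant carries a latent offset drawn from
``Normal(0, subject_sd)`` on the logit scale (the random-intercept structure
of the study designs).  Their probability of calling a stimulus a "word" is

    p = sigmoid(logit(p_word[condition, stimulus_type]) + offset)

and each of the 12 trials per condition (4 words, 4 part-words of each
class) is an independent Bernoulli draw from p.  A response is *correct*
when a statistical word is accepted or a part-word is rejected.

Two presets ship with the package.  ``GUESSING`` has p_word = 0.5 everywhere
with no subject variance and calibrates chance-level machinery.
``CUE_PATTERN`` encodes the qualitative behavioral pattern reported for
this paradigm — pauses help most, lengthening helps, shortening reverses the
percept (part-words 2-1 are massively accepted as words), pitch moves little
— with illustrative probabilities; only the ordering of effects is
meaningful, not the magnitudes.

Three experimental layouts are supported: a between-subjects design (each
participant sees one of six conditions), a within-subjects design over four
conditions, and a within-subjects design where each participant is assigned
baseline + pause + one durational + one pitch condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .items import STIMULUS_TYPES
from .prosody import CONDITION_NAMES

__all__ = [
    "ResponseModel",
    "DesignSpec",
    "ResponseRecord",
    "GUESSING",
    "CUE_PATTERN",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "EXP3_DESIGN",
    "simulate_responses",
    "records_to_frame",
]

_TRIALS_PER_TYPE = 4  # 4 WORD + 4 PW12 + 4 PW21 = 12 trials per condition


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1 / (1 + np.exp(-x))


@dataclass(frozen=True)
class ResponseModel:
    """Per-cell probabilities of answering "word", plus subject variance."""

    p_word: dict[tuple[str, str], float]
    subject_sd: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for cell, p in self.p_word.items():
            if not 0 < p < 1:
                raise ValueError(f"p_word{cell} = {p} outside (0, 1)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")

    def cell(self, condition: str, stimulus_type: str) -> float:
        try:
            return self.p_word[(condition, stimulus_type)]
        except KeyError:
            raise KeyError(
                f"response model {self.name!r} has no cell ({condition}, {stimulus_type})"
            ) from None


def _uniform_model(p: float, sd: float, name: str) -> ResponseModel:
    cells = {(c, s): p for c in CONDITION_NAMES for s in STIMULUS_TYPES}
    return ResponseModel(p_word=cells, subject_sd=sd, name=name)


GUESSING = _uniform_model(0.5, 0.0, "guessing")

#: Illustrative probabilities reproducing the ordinal behavioral pattern:
#: pause > lengthening > baseline ~ pitch (all above chance), shortening
#: below chance with part-words 2-1 mostly accepted as words.
CUE_PATTERN = ResponseModel(
    p_word={
        ("baseline", "WORD"): 0.75, ("baseline", "PW12"): 0.35, ("baseline", "PW21"): 0.35,
        ("pause", "WORD"): 0.92, ("pause", "PW12"): 0.12, ("pause", "PW21"): 0.12,
        ("lengthening", "WORD"): 0.88, ("lengthening", "PW12"): 0.16, ("lengthening", "PW21"): 0.16,
        ("shortening", "WORD"): 0.40, ("shortening", "PW12"): 0.30, ("shortening", "PW21"): 0.80,
        ("pitch_up", "WORD"): 0.72, ("pitch_up", "PW12"): 0.38, ("pitch_up", "PW21"): 0.38,
        ("pitch_down", "WORD"): 0.70, ("pitch_down", "PW12"): 0.40, ("pitch_down", "PW21"): 0.40,
    },
    subject_sd=0.5,
    name="cue_pattern",
)


@dataclass(frozen=True)
class DesignSpec:
    """Participant-to-condition layout of one experiment."""

    layout: str  # BETWEEN | WITHIN_ALL4 | WITHIN_4OF6
    n_participants: int
    conditions: tuple[str, ...]
    condition_ns: tuple[int, ...] | None = None  # BETWEEN only: per-condition group sizes
    languages: tuple[str, ...] = ("language0",)

    def __post_init__(self) -> None:
        if self.layout == "BETWEEN":
            ns = self.condition_ns
            if ns is None or len(ns) != len(self.conditions):
                raise ValueError("BETWEEN layout needs one group size per condition")
            if sum(ns) != self.n_participants:
                raise ValueError("condition_ns must sum to n_participants")
        elif self.layout not in ("WITHIN_ALL4", "WITHIN_4OF6"):
            raise ValueError(f"unknown layout {self.layout!r}")


#: The three study designs: 202 participants across six conditions
#: (33/33/33 pause, lengthening, pitch_up; 34/34 baseline, shortening;
#: 35 pitch_down), 34 participants x 4 conditions within-subjects, and
#: 42 participants x 4-of-6 conditions within-subjects.
EXP1_DESIGN = DesignSpec(
    layout="BETWEEN",
    n_participants=202,
    conditions=("baseline", "pause", "lengthening", "shortening", "pitch_up", "pitch_down"),
    condition_ns=(34, 33, 33, 34, 33, 35),
    languages=("language0",),
)
EXP2_DESIGN = DesignSpec(
    layout="WITHIN_ALL4",
    n_participants=34,
    conditions=("baseline", "pause", "lengthening", "shortening"),
    languages=("language1", "language2", "language3", "language4"),
)
EXP3_DESIGN = DesignSpec(
    layout="WITHIN_4OF6",
    n_participants=42,
    conditions=("baseline", "pause", "lengthening", "shortening", "pitch_up", "pitch_down"),
    languages=("language1", "language2", "language3", "language4"),
)


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: int
    condition: str
    language_id: str
    condition_order: int  # presentation rank of the condition for this participant
    trial_index: int  # 0..11 within condition
    stimulus_type: str  # WORD | PW12 | PW21
    response: str  # WORD_YES | WORD_NO
    correct: bool


def _assign_conditions(
    design: DesignSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Per-participant condition lists (in presentation order)."""
    if design.layout == "BETWEEN":
        pool = [
            cond
            for cond, n in zip(design.conditions, design.condition_ns)  # type: ignore[arg-type]
            for _ in range(n)
        ]
        rng.shuffle(pool)
        return [(c,) for c in pool]
    if design.layout == "WITHIN_ALL4":
        out = []
        for _ in range(design.n_participants):
            order = list(design.conditions)
            rng.shuffle(order)
            out.append(tuple(order))
        return out
    # WITHIN_4OF6: baseline + pause + one durational + one pitch condition,
    # with the 4 durational-x-pitch assignments balanced across participants.
    combos = [
        (dur, pitch)
        for dur in ("lengthening", "shortening")
        for pitch in ("pitch_up", "pitch_down")
    ]
    n = design.n_participants
    assignment = [combos[i % 4] for i in range(n)]
    rng.shuffle(assignment)
    out = []
    for dur, pitch in assignment:
        order = ["baseline", "pause", dur, pitch]
        rng.shuffle(order)
        out.append(tuple(order))
    return out


def _assign_languages(
    design: DesignSpec, n_conditions: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """A pseudo-random language per condition slot (no within-subject reuse)."""
    if len(design.languages) == 1:
        return design.languages * n_conditions
    langs = list(design.languages)
    rng.shuffle(langs)
    return tuple(langs[:n_conditions])


def simulate_responses(
    design: DesignSpec, model: ResponseModel, seed: int
) -> list[ResponseRecord]:
    """Simulate every participant's binary judgments for a design.

    Deterministic given ``seed``.  Record count is
    ``sum over participants of (assigned conditions) * 12``.
    """
    rng = np.random.default_rng(seed)
    # fail fast if the model lacks any cell of the design
    for cond in design.conditions:
        for stype in STIMULUS_TYPES:
            model.cell(cond, stype)

    condition_lists = _assign_conditions(design, rng)
    records: list[ResponseRecord] = []
    for pid, conditions in enumerate(condition_lists):
        offset = rng.normal(0.0, model.subject_sd) if model.subject_sd > 0 else 0.0
        languages = _assign_languages(design, len(conditions), rng)
        for order, (cond, lang) in enumerate(zip(conditions, languages)):
            stypes = [s for s in STIMULUS_TYPES for _ in range(_TRIALS_PER_TYPE)]
            rng.shuffle(stypes)
            p = {
                s: float(_sigmoid(_logit(model.cell(cond, s)) + offset))
                for s in STIMULUS_TYPES
            }
            draws = rng.random(len(stypes))
            for trial, (stype, u) in enumerate(zip(stypes, draws)):
                yes = bool(u < p[stype])
                records.append(
                    ResponseRecord(
                        participant_id=pid,
                        condition=cond,
                        language_id=lang,
                        condition_order=order,
                        trial_index=trial,
                        stimulus_type=stype,
                        response="WORD_YES" if yes else "WORD_NO",
                        correct=yes if stype == "WORD" else not yes,
                    )
                )
    return records


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Long-format DataFrame, one row per simulated judgment."""
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in records],
            "condition": [r.condition for r in records],
            "language": [r.language_id for r in records],
            "order": [r.condition_order for r in records],
            "trial": [r.trial_index for r in records],
            "stimulus_type": [r.stimulus_type for r in records],
            "response": [r.response for r in records],
            "correct": [r.correct for r in records],
        }
    )
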