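"""Prosodic cue conditions: per-token duration, f0, pause and amplitude.

Six conditions share a common base (every syllable 500 ms at 210 Hz) and
differ only in what happens on or after word-final syllables:

===========  ==================  =========  =================
condition    final duration      final f0   pause after final
===========  ==================  =========  =================
baseline     500 ms              210 Hz     0 ms
pause        500 ms              210 Hz     250 ms
lengthening  750 ms (+50%)       210 Hz     0 ms
shortening   250 ms (-50%)       210 Hz     0 ms
pitch_up     500 ms              260 Hz     0 ms
pitch_down   500 ms              160 Hz     0 ms
===========  ==================  =========  =================

A pause is emitted after every word including the stream-final one, which
makes the closed-form stream durations exact (70 s for a 40-word pause
stream, 168 s for a 96-word one).  The fade-in/fade-out ramps the amplitude
of the first and last 15 syllables in steps of exactly 1/15 so that word
boundaries are not cued by the stream edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .stream import Position, SyllableToken

__all__ = [
    "ConditionSpec",
    "ProsodicToken",
    "ProsodicStream",
    "CONDITIONS",
    "CONDITION_NAMES",
    "apply_condition",
    "fade_envelope",
    "stream_duration",
]

BASE_DURATION_MS = 500
BASE_F0_HZ = 210
FADE_SYLLABLES = 15


@dataclass(frozen=True)
class ConditionSpec:
    """Acoustic targets for one experimental condition."""

    name: str
    base_duration: int = BASE_DURATION_MS  # ms, non-final syllables
    base_f0: int = BASE_F0_HZ  # Hz
    final_duration: int = BASE_DURATION_MS  # ms, word-final syllables
    final_f0: int = BASE_F0_HZ  # Hz
    pause_after_final: int = 0  # ms of silence after word-final syllables


CONDITIONS: dict[str, ConditionSpec] = {
    "baseline": ConditionSpec("baseline"),
    "pause": ConditionSpec("pause", pause_after_final=250),
    "lengthening": ConditionSpec("lengthening", final_duration=750),
    "shortening": ConditionSpec("shortening", final_duration=250),
    "pitch_up": ConditionSpec("pitch_up", final_f0=260),
    "pitch_down": ConditionSpec("pitch_down", final_f0=160),
}

CONDITION_NAMES = tuple(CONDITIONS)


@dataclass(frozen=True)
class ProsodicToken:
    """A syllable token annotated with its acoustic targets."""

    token: SyllableToken
    duration: int  # ms
    f0: int  # Hz
    pause_after: int  # ms
    amp_scale: float = 1.0  # fraction of peak amplitude in (0, 1]


@dataclass(frozen=True)
class ProsodicStream:
    tokens: tuple[ProsodicToken, ...]
    condition: ConditionSpec

    def __len__(self) -> int:
        return len(self.tokens)


def apply_condition(tokens: list[SyllableToken], condition: ConditionSpec | str) -> ProsodicStream:
    """Annotate a symbolic stream with one condition's acoustic targets.

    Cues land on (duration, f0) or after (pause) word-final syllables only;
    all other syllables carry the base values.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    if not tokens:
        raise ValueError("empty token stream")
    out = []
    for tok in tokens:
        final = tok.position is Position.FINAL
        out.append(
            ProsodicToken(
                token=tok,
                duration=condition.final_duration if final else condition.base_duration,
                f0=condition.final_f0 if final else condition.base_f0,
                pause_after=condition.pause_after_final if final else 0,
            )
        )
    return ProsodicStream(tokens=tuple(out), condition=condition)


def fade_envelope(stream: ProsodicStream) -> ProsodicStream:
    """Set the fade-in/fade-out amplitude schedule.

    Syllable k (1-based, k <= 15) gets amp_scale = k/15; the last 15
    syllables mirror this descending, so the final syllable sits at 1/15.
    """
    n = len(stream)
    if n < 2 * FADE_SYLLABLES:
        raise ValueError(f"fade envelope needs >= {2 * FADE_SYLLABLES} tokens, got {n}")
    faded = []
    for i, tok in enumerate(stream.tokens):
        k = i + 1
        from_end = n - i
        if k <= FADE_SYLLABLES:
            scale = k / FADE_SYLLABLES
        elif from_end <= FADE_SYLLABLES:
            scale = from_end / FADE_SYLLABLES
        else:
            scale = 1.0
        faded.append(replace(tok, amp_scale=scale))
    return ProsodicStream(tokens=tuple(faded), condition=stream.condition)


def stream_duration(stream: ProsodicStream) -> float:
    """Total stream duration in seconds (syllables plus pauses)."""
    total_ms = sum(t.duration + t.pause_after for t in stream.tokens)
    return total_ms / 1000.0
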