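"""Parametric audio rendering of prosodic streams to WAV.

Syllables are synthesized parametrically: a brief broadband noise burst
stands in for the consonant onset and a harmonic complex at the token's f0
for the vowel.  The burst occupies the first 20 ms of every syllable and is
never stretched or compressed by durational cues (protecting the
voice-onset region); durational changes act on the voiced remainder only.
Each syllable is peak-normalized to ``peak_amplitude * amp_scale`` and
pauses are rendered as exact digital silence.

Output is 16-bit PCM mono WAV (via :mod:`scipy.io.wavfile`) plus a sidecar
JSON manifest listing every segment's half-open sample interval
``[onset, offset)`` and token metadata, so that segment durations can be
verified sample-exactly downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .prosody import ProsodicStream

__all__ = ["RenderConfig", "RenderResult", "render", "read_wav"]

_BURST_SEED = 20210316  # fixed consonant-burst noise seed (rendering is deterministic)
_N_HARMONICS = 10


@dataclass(frozen=True)
class RenderConfig:
    sample_rate: int = 44_100  # Hz
    peak_amplitude: float = 0.99
    onset_protect_ms: int = 20  # consonant burst length, exempt from stretching
    synthesis_backend: str = "harmonic"

    def __post_init__(self) -> None:
        if self.sample_rate < 8_000:
            raise ValueError("sample_rate must be >= 8000 Hz")
        if not 0 < self.peak_amplitude <= 1:
            raise ValueError("peak_amplitude must be in (0, 1]")


@dataclass
class RenderResult:
    samples: np.ndarray  # float64 in [-1, 1]
    sample_rate: int
    manifest: list[dict]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _syllable_waveform(
    duration_ms: int, f0: int, config: RenderConfig, rng: np.random.Generator
) -> np.ndarray:
    """One syllable: 20 ms noise burst followed by a harmonic complex at f0."""
    sr = config.sample_rate
    if f0 * 2 > sr:
        raise ValueError(f"sample rate {sr} too low to represent f0 {f0}")
    n_total = round(duration_ms * sr / 1000)
    n_burst = min(round(config.onset_protect_ms * sr / 1000), n_total)
    burst = rng.uniform(-1.0, 1.0, size=n_burst) * np.linspace(1.0, 0.3, n_burst)
    if n_burst > 0:
        # burst peak fixed below the voiced peak so the syllable peak is set by
        # the vowel and the onset waveform is bit-identical across durations
        burst *= 0.8 / np.max(np.abs(burst))

    n_voiced = n_total - n_burst
    t = np.arange(n_voiced) / sr
    voiced = np.zeros(n_voiced)
    for h in range(1, _N_HARMONICS + 1):
        if h * f0 * 2 >= sr:
            break
        voiced += np.sin(2 * np.pi * h * f0 * t) / h
    # short raised-cosine edges so concatenation is click-free
    n_ramp = min(round(0.005 * sr), n_voiced // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp)))
        voiced[:n_ramp] *= ramp
        voiced[-n_ramp:] *= ramp[::-1]
    peak = np.max(np.abs(voiced)) if n_voiced else 0.0
    if peak > 0:
        voiced /= peak
    return np.concatenate([burst, voiced])


def render(
    stream: ProsodicStream,
    config: RenderConfig | None = None,
    path: str | Path | None = None,
) -> RenderResult:
    """Render a (fade-enveloped) prosodic stream to PCM samples.

    Each syllable segment is exactly ``round(duration_ms * sr / 1000)``
    samples and peak-normalized to ``peak_amplitude * amp_scale``; pauses are
    all-zero segments.  When ``path`` is given, a 16-bit mono WAV is written
    there together with a ``<path>.manifest.json`` sidecar.
    """
    config = config or RenderConfig()
    if config.synthesis_backend != "harmonic":
        raise ValueError(f"unknown synthesis backend {config.synthesis_backend!r}")
    rng = np.random.default_rng(_BURST_SEED)
    sr = config.sample_rate
    pieces: list[np.ndarray] = []
    manifest: list[dict] = []
    cursor = 0
    for tok in stream.tokens:
        wave = _syllable_waveform(tok.duration, tok.f0, config, rng)
        wave = wave * (config.peak_amplitude * tok.amp_scale)
        pieces.append(wave)
        manifest.append(
            {
                "kind": "syllable",
                "syllable": str(tok.token.syllable),
                "word_index": tok.token.word_index,
                "position": tok.token.position.value,
                "onset": cursor,
                "offset": cursor + len(wave),
                "duration_ms": tok.duration,
                "f0_hz": tok.f0,
                "amp_scale": tok.amp_scale,
            }
        )
        cursor += len(wave)
        if tok.pause_after > 0:
            n_pause = round(tok.pause_after * sr / 1000)
            pieces.append(np.zeros(n_pause))
            manifest.append(
                {
                    "kind": "pause",
                    "onset": cursor,
                    "offset": cursor + n_pause,
                    "duration_ms": tok.pause_after,
                }
            )
            cursor += n_pause
    samples = np.concatenate(pieces) if pieces else np.zeros(0)
    result = RenderResult(samples=samples, sample_rate=sr, manifest=manifest)
    if path is not None:
        path = Path(path)
        pcm = np.clip(np.round(samples * 32767), -32768, 32767).astype(np.int16)
        wavfile.write(path, sr, pcm)
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )
    return result


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a 16-bit WAV back as (sample_rate, float samples in [-1, 1])."""
    sr, pcm = wavfile.read(path)
    return sr, pcm.astype(np.float64) / 32767.0
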