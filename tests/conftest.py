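"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from seglab import lexicon, stream


@pytest.fixture(scope="session")
def language0():
    return lexicon.TABLE1_LANGUAGES[0]


@pytest.fixture(scope="session")
def language1():
    return lexicon.TABLE1_LANGUAGES[1]


@pytest.fixture(scope="session")
def tokens40(language0):
    """A 40-word Experiment-1-scale stream (120 syllable tokens)."""
    order = stream.generate_word_order(n_repeats=10, seed=11)
    return stream.build_stream(language0, order)


@pytest.fixture(scope="session")
def tokens96(language1):
    """A 96-word Experiment-2-scale stream (288 syllable tokens)."""
    order = stream.generate_word_order(n_repeats=24, seed=12)
    return stream.build_stream(language1, order)


def adjusted(rate: float, n: int) -> float:
    """Independent restatement of the 1/(2N) boundary rule."""
    return 1 / (2 * n) if rate == 0 else (1 - 1 / (2 * n) if rate == 1 else rate)


def expected_dprime(
    p_word: float,
    p_pw12: float,
    p_pw21: float,
    subject_sd: float = 0.0,
    n_quad: int = 61,
) -> float:
    """Analytic mean d' implied by a cell of the response model.

    Enumerates the 4-trial hit count and the two 4-trial false-alarm counts
    exactly (binomial pmfs), applies the 1/(2N) adjustment to each realized
    rate, and integrates the participant logit offset by Gauss-Hermite
    quadrature.  Fully independent of the package's simulation/analysis path.
    """
    if subject_sd > 0:
        xs, ws = np.polynomial.hermite_e.hermegauss(n_quad)
        offsets, weights = xs * subject_sd, ws / ws.sum()
    else:
        offsets, weights = np.array([0.0]), np.array([1.0])

    logits = [np.log(p / (1 - p)) for p in (p_word, p_pw12, p_pw21)]
    z = sps.norm.ppf
    total = 0.0
    for off, w in zip(offsets, weights):
        qh, q12, q21 = (1 / (1 + np.exp(-(l + off))) for l in logits)
        hz = sum(
            sps.binom.pmf(h, 4, qh) * z(adjusted(h / 4, 4)) for h in range(5)
        )
        fz = sum(
            sps.binom.pmf(f1, 4, q12)
            * sps.binom.pmf(f2, 4, q21)
            * z(adjusted((f1 + f2) / 8, 8))
            for f1 in range(5)
            for f2 in range(5)
        )
        total += w * (hz - fz)
    return float(total)
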