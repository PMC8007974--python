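"""Signal-detection computations: 1/(2N) rule, d', summaries, export."""

from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seglab import sdt, simulate
from seglab.sdt import (
    DPrimeResult,
    SDTCounts,
    adjust_rates,
    d_prime,
    export_long_format,
    group_summary,
    import_long_format,
    participant_d_primes,
    proportion_correct,
)

# independent normal-quantile oracle (stdlib, not scipy)
_z = NormalDist().inv_cdf


class TestAdjustRates:
    def test_perfect_hits_pulled_down(self):
        hit, _ = adjust_rates(SDTCounts(hits=4, misses=0, false_alarms=2, correct_rejections=6))
        assert hit == 0.875  # 1 - 1/(2*4)

    def test_zero_false_alarms_pulled_up(self):
        _, fa = adjust_rates(SDTCounts(hits=3, misses=1, false_alarms=0, correct_rejections=8))
        assert fa == 0.0625  # 1/(2*8)

    def test_interior_rates_unchanged(self):
        hit, fa = adjust_rates(SDTCounts(hits=2, misses=2, false_alarms=4, correct_rejections=4))
        assert (hit, fa) == (0.5, 0.5)

    def test_per_rate_n_not_pooled(self):
        """The rule uses N of the respective rate: 4 for hits, 8 for FAs."""
        hit, fa = adjust_rates(SDTCounts(hits=4, misses=0, false_alarms=0, correct_rejections=8))
        assert hit == 1 - 1 / 8 and fa == 1 / 16

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            adjust_rates(SDTCounts(hits=0, misses=0, false_alarms=1, correct_rejections=7))


class TestDPrime:
    def test_chance_is_zero(self):
        res = d_prime(SDTCounts(hits=2, misses=2, false_alarms=4, correct_rejections=4))
        assert res.d_prime == pytest.approx(0.0)

    def test_perfect_performance(self):
        res = d_prime(SDTCounts(hits=4, misses=0, false_alarms=0, correct_rejections=8))
        assert res.d_prime == pytest.approx(_z(0.875) - _z(0.0625))
        assert res.d_prime == pytest.approx(2.684, abs=1e-3)

    def test_symmetric_rates(self):
        res = d_prime(SDTCounts(hits=3, misses=1, false_alarms=2, correct_rejections=6))
        assert res.d_prime == pytest.approx(_z(0.75) - _z(0.25))
        assert res.d_prime == pytest.approx(1.349, abs=1e-3)

    @given(
        hits=st.integers(0, 4),
        fas=st.integers(0, 8),
        more_hits=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_hits_and_fas(self, hits, fas, more_hits):
        """d' strictly increases with hits and strictly decreases with FAs."""
        base = d_prime(SDTCounts(hits, 4 - hits, fas, 8 - fas)).d_prime
        h2 = min(4, hits + more_hits)
        if h2 > hits:
            assert d_prime(SDTCounts(h2, 4 - h2, fas, 8 - fas)).d_prime > base
        f2 = min(8, fas + more_hits)
        if f2 > fas:
            assert d_prime(SDTCounts(hits, 4 - hits, f2, 8 - f2)).d_prime < base


class TestGroupSummary:
    def test_degenerate_all_zero(self):
        table = pd.DataFrame({"condition": ["a"] * 5, "d_prime": [0.0] * 5})
        (summary,) = group_summary(table)
        assert summary.mean_d_prime == summary.ci_low == summary.ci_high == 0.0
        assert not summary.excludes_zero

    def test_single_participant_errors(self):
        table = pd.DataFrame({"condition": ["a"], "d_prime": [1.0]})
        with pytest.raises(ValueError):
            group_summary(table)

    def test_t_interval_matches_closed_form(self):
        from scipy import stats as sps

        values = [0.2, 0.8, 1.1, 0.5, 0.9, 0.3]
        table = pd.DataFrame({"condition": ["c"] * 6, "d_prime": values})
        (summary,) = group_summary(table)
        mean = np.mean(values)
        half = sps.t.ppf(0.975, 5) * np.std(values, ddof=1) / np.sqrt(6)
        assert summary.mean_d_prime == pytest.approx(mean)
        assert summary.ci_low == pytest.approx(mean - half)
        assert summary.ci_high == pytest.approx(mean + half)


class TestProportionCorrect:
    def test_toy_table_hand_computed(self):
        """Cell means equal hand-computed proportions on a 3-participant table."""
        recs = []
        # participant 0: all correct on WORD; 1: half; 2: none
        for pid, n_yes in [(0, 4), (1, 2), (2, 0)]:
            for t in range(4):
                yes = t < n_yes
                recs.append(
                    simulate.ResponseRecord(
                        participant_id=pid, condition="baseline", language_id="language0",
                        condition_order=0, trial_index=t, stimulus_type="WORD",
                        response="WORD_YES" if yes else "WORD_NO", correct=yes,
                    )
                )
        table = proportion_correct(recs, n_bootstrap=50, seed=0)
        assert len(table) == 1
        assert table.loc[0, "mean_correct"] == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            proportion_correct([])


def test_participant_dprimes_shape():
    recs = simulate.simulate_responses(simulate.EXP2_DESIGN, simulate.GUESSING, seed=1)
    table = participant_d_primes(recs)
    assert len(table) == 34 * 4
    assert ((table["hits"] + table["misses"]) == 4).all()
    assert ((table["false_alarms"] + table["correct_rejections"]) == 8).all()
    assert table["adj_hit_rate"].between(0, 1, inclusive="neither").all()
    assert table["adj_fa_rate"].between(0, 1, inclusive="neither").all()


def test_export_round_trip(tmp_path):
    recs = simulate.simulate_responses(simulate.EXP1_DESIGN, simulate.GUESSING, seed=2)
    path = export_long_format(recs, tmp_path / "responses.csv")
    text = path.read_text().splitlines()
    assert len(text) == 2424 + 1  # header + one row per judgment
    back = import_long_format(path)
    pd.testing.assert_frame_equal(back, simulate.records_to_frame(recs))


def test_export_empty_is_header_only(tmp_path):
    path = export_long_format([], tmp_path / "empty.csv")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("participant,")
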