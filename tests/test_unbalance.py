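"""Entropy unbalance: windowed entropy, Gamma, UD/UI, identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fnirs_macorr import (
    entropy_series,
    gamma_correlation,
    identify_contaminated,
    neighbor_mean_entropy,
    signal_entropy,
    stop_criterion,
    unbalance_report,
)
from fnirs_macorr.unbalance import EntropySeries, UnbalanceReport, mean_abs_deviation


def entropy_loop(window):
    """Independent brute-force oracle for the entropy sum."""
    total = 0.0
    for a in window:
        if a != 0:
            total += a * np.log2(abs(a))
    return -total


class TestSignalEntropy:
    def test_zero_window_convention(self):
        assert signal_entropy(np.zeros(20)) == 0.0

    def test_two_halves(self):
        assert signal_entropy([0.5, 0.5]) == pytest.approx(1.0)

    @given(arrays(float, 20, elements=st.floats(-2, 2, allow_nan=False, width=32)))
    @settings(max_examples=100, deadline=None)
    def test_matches_elementwise_loop(self, w):
        assert signal_entropy(w) == pytest.approx(entropy_loop(w), abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            signal_entropy([])


class TestEntropySeries:
    def test_constant_zero_signal(self):
        es = entropy_series(np.zeros(100), 20)
        assert not es.values.any()
        assert len(es.values) == 100

    def test_matches_sliding_window_oracle(self, rng):
        x = rng.normal(size=157)
        n = 20
        es = entropy_series(x, n)
        lpad, rpad = n // 2, (n + 1) // 2 - 1
        pad = np.concatenate([x[:lpad][::-1], x, x[-rpad:][::-1] if rpad else x[:0]])
        for k in range(x.size):
            expected = entropy_loop(pad[k : k + n]) / n
            assert es.values[k] == pytest.approx(expected, abs=1e-12)

    def test_window_spans_two_seconds_at_10hz(self):
        # the default 20-sample window covers 2 s of a 10 Hz signal
        es = entropy_series(np.ones(50), 20)
        assert es.window_n == 20
        assert es.window_n / 10.0 == 2.0

    @pytest.mark.parametrize("n", [0, -3, 100])
    def test_invalid_window_rejected(self, n):
        with pytest.raises(ValueError):
            entropy_series(np.ones(100), n)


class TestNeighborMeanAndGamma:
    def test_single_remaining_neighbor_passthrough(self, layout5, rng):
        series = {c: EntropySeries(c, rng.normal(size=30), 20) for c in layout5.channel_ids}
        # T3 has channels {4, 9}: excluding 4 leaves only CH9
        out = neighbor_mean_entropy(series, layout5, "T3", 4)
        assert np.array_equal(out, series[9].values)

    def test_two_neighbor_mean(self, layout5, rng):
        series = {c: EntropySeries(c, rng.normal(size=30), 20) for c in layout5.channel_ids}
        out = neighbor_mean_entropy(series, layout5, "R2", 4)
        assert np.allclose(out, (series[3].values + series[8].values) / 2)

    def test_ch20_mean_around_r6(self, layout5, rng):
        series = {c: EntropySeries(c, rng.normal(size=30), 20) for c in layout5.channel_ids}
        out = neighbor_mean_entropy(series, layout5, "R6", 20)
        expected = np.mean([series[c].values for c in (15, 19, 24)], axis=0)
        assert np.allclose(out, expected)

    def test_non_incident_channel_rejected(self, layout5, rng):
        series = {c: EntropySeries(c, rng.normal(size=30), 20) for c in layout5.channel_ids}
        with pytest.raises(ValueError):
            neighbor_mean_entropy(series, layout5, "R2", 20)

    def test_gamma_zeros_and_ones(self):
        assert gamma_correlation(np.zeros(5), np.ones(5)) == 0.0
        assert gamma_correlation(np.ones(3), np.ones(3)) == 3.0

    def test_gamma_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=64), rng.normal(size=64)
        expected = sum(float(a[i]) * float(b[i]) for i in range(64))
        assert gamma_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_gamma_length_mismatch(self):
        with pytest.raises(ValueError):
            gamma_correlation(np.ones(3), np.ones(4))


class TestUnbalanceReport:
    def test_identical_channels_perfectly_balanced(self, layout5, rng):
        x = rng.normal(size=200)
        rec = np.tile(x, (40, 1))
        rep = unbalance_report(rec, layout5)
        assert all(abs(v) < 1e-9 for v in rep.ud.values())
        assert all(abs(v) < 1e-8 for v in rep.ui.values())

    def test_ud_is_absolute_gamma_difference(self, clean_recording, layout5):
        rep = unbalance_report(clean_recording.observed, layout5)
        for ch, (g_t, g_r) in rep.gamma.items():
            assert rep.ud[ch] == pytest.approx(abs(g_t - g_r), abs=1e-12)

    def test_ui_sums_incident_ud(self, clean_recording, layout5):
        rep = unbalance_report(clean_recording.observed, layout5)
        for o in layout5.optodes:
            expected = sum(rep.ud[c] for c in layout5.neighbor_channels(o.id))
            assert rep.ui[o.id] == pytest.approx(expected, abs=1e-9)

    def test_scaling_a_channel_perturbs_its_ud(self, clean_recording, layout5):
        rec = clean_recording.observed.copy()
        rep0 = unbalance_report(rec, layout5)
        rec[layout5.channel_ids.index(20)] *= 3.0
        rep1 = unbalance_report(rec, layout5)
        assert rep1.ud[20] != pytest.approx(rep0.ud[20], rel=1e-3)

    def test_too_short_recording_rejected(self, layout5):
        with pytest.raises(ValueError):
            unbalance_report(np.zeros((40, 10)), layout5, n=20)


class TestIdentification:
    def test_jump_at_t3_implicates_r2_or_r5(self, jump_recording, layout5):
        rep = unbalance_report(jump_recording.observed, layout5)
        triple = identify_contaminated(rep, layout5)
        assert triple.contaminated
        assert triple.r_optode in ("R2", "R5")
        assert triple.channel in (4, 9)
        assert triple.t_optode == "T3"

    def test_matches_exhaustive_argmax_oracle(self, layout5, rng):
        for _ in range(10):
            ud = {c: float(rng.uniform(0, 1)) for c in layout5.channel_ids}
            ui = {
                o.id: sum(ud[c] for c in layout5.neighbor_channels(o.id))
                for o in layout5.optodes
            }
            rep = UnbalanceReport({c: (ud[c], 0.0) for c in ud}, ud, ui)
            triple = identify_contaminated(rep, layout5, outlier_k=0.0)
            r_ui = {o: ui[o] for o in ui if o.startswith("R")}
            best_r = max(sorted(r_ui), key=lambda o: r_ui[o])
            incident = layout5.neighbor_channels(best_r)
            best_ch = max(sorted(incident), key=lambda c: ud[c])
            assert triple.r_optode == best_r
            assert triple.channel == best_ch
            assert triple.t_optode == layout5.optodes_of_channel(best_ch)[0]

    def test_all_zero_report_flags_no_contamination(self, layout5):
        ud = {c: 0.0 for c in layout5.channel_ids}
        ui = {o.id: 0.0 for o in layout5.optodes}
        rep = UnbalanceReport({c: (0.0, 0.0) for c in ud}, ud, ui)
        triple = identify_contaminated(rep, layout5)
        assert not triple.contaminated
        assert triple.r_optode == "R1"
        assert triple.channel == min(layout5.neighbor_channels("R1"))

    def test_clean_recording_not_flagged(self, clean_recording, layout5):
        rep = unbalance_report(clean_recording.observed, layout5)
        assert not identify_contaminated(rep, layout5).contaminated


class TestStopCriterion:
    def test_identical_uis_stop(self):
        assert stop_criterion([3.0, 3.0, 3.0], sigma_th=1e-6)

    def test_spread_uis_do_not_stop(self):
        assert not stop_criterion([0.0, 10.0], sigma_th=1.0)  # MAD = 5

    @given(arrays(float, st.integers(1, 30), elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_mad(self, v):
        mad = float(np.mean(np.abs(v - v.mean())))
        assert stop_criterion(v, mad + 1e-9)
        if mad > 0:
            assert not stop_criterion(v, mad / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stop_criterion([], 1.0)

    def test_mad_helper(self):
        assert mean_abs_deviation([0.0, 10.0]) == 5.0
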