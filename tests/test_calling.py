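"""Robust thresholds, the positivity state machine, classification, statistics."""

import itertools

import numpy as np
import pytest

from qlcis import (
    CssTrace,
    ThresholdSet,
    activation_curve,
    call_positive,
    classify_activity,
    compare_groups,
    kmeans_concordance,
    robust_sd,
    significance_label,
)


def trace(values, interval=1.0):
    return CssTrace(values=np.asarray(values, dtype=float),
                    frame_interval=interval, time_unit="h", channel="IL-5")


def trace_from_pattern(pattern, sigma=1.0, hi=5.0, lo=0.0):
    """Binary supra/sub pattern -> CSS values around a 3*sigma threshold."""
    return trace([hi * sigma if b else lo for b in pattern])


def oracle_positive(pattern, min_run=2, max_gap=3):
    """Brute-force re-statement of the published rule on a binary pattern.

    Group the supra-threshold frame indices such that consecutive supra
    frames separated by at most max_gap sub frames share a group; the
    pattern is positive iff some group holds >= min_run supra frames, with
    onset at that group's first frame.
    """
    idx = [i for i, b in enumerate(pattern) if b]
    groups = []
    for i in idx:
        if groups and i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    for g in groups:
        if len(g) >= min_run:
            return True, g[0]
    return False, None


class TestRobustSD:
    def test_forced_arithmetic_small_list(self):
        """{1,2,3,4,5}: MAD = 1, so sigma is exactly the 1.4826 factor."""
        res = robust_sd([1, 2, 3, 4, 5])
        assert res.sigma == 1.4826
        assert not res.degenerate

    def test_constant_list_degenerate(self):
        res = robust_sd([7.0] * 10)
        assert res.sigma == 0.0 and res.degenerate

    def test_gaussian_consistency(self):
        """1.4826*MAD estimates unit SD within 2% on 1e5 normal draws."""
        x = np.random.default_rng(7).standard_normal(100_000)
        assert abs(robust_sd(x).sigma - 1.0) < 0.02

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            robust_sd([1.0, 2.0])

    def test_outlier_resistant(self):
        x = np.concatenate([np.random.default_rng(1).standard_normal(1000),
                            np.full(50, 1e6)])
        assert abs(robust_sd(x).sigma - 1.0) < 0.1


class TestCallPositive:
    TH = ThresholdSet(sigma=1.0)

    def test_all_zero_trace_negative(self):
        call = call_positive(trace(np.zeros(30)), self.TH)
        assert not call.positive and call.onset_frame is None

    def test_two_consecutive_supra_frames_positive(self):
        """Exactly two supra frames confirm positivity; onset is the first."""
        call = call_positive(trace_from_pattern([0, 0, 1, 1, 0, 0]), self.TH)
        assert call.positive and call.onset_frame == 2

    def test_single_supra_frame_negative(self):
        call = call_positive(trace_from_pattern([0, 1, 0, 0, 0]), self.TH)
        assert not call.positive

    def test_three_frame_gap_bridged(self):
        """supra x5, sub x3, supra x5 is one episode spanning all 13 frames."""
        pattern = [1] * 5 + [0] * 3 + [1] * 5
        call = call_positive(trace_from_pattern(pattern), self.TH)
        assert call.positive
        assert call.episodes == [(0, 12)]

    def test_four_frame_gap_splits_episodes(self):
        pattern = [1] * 5 + [0] * 4 + [1] * 5
        call = call_positive(trace_from_pattern(pattern), self.TH)
        assert call.episodes == [(0, 4), (9, 13)]

    def test_repeated_gaps_allowed_within_episode(self):
        pattern = [1, 0, 0, 1, 0, 0, 1]
        call = call_positive(trace_from_pattern(pattern), self.TH)
        assert call.positive and call.episodes == [(0, 6)]

    def test_onset_time_scales_with_frame_interval(self):
        call = call_positive(trace_from_pattern([0, 0, 1, 1], ), self.TH)
        assert call.onset_time == pytest.approx(2.0)

    def test_threshold_boundary_inclusive(self):
        """A frame exactly at the detection limit counts as supra."""
        call = call_positive(trace([3.0, 3.0, 0.0]), self.TH)
        assert call.positive

    def test_monotone_in_threshold(self):
        """Raising the threshold never creates a positive call."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            values = rng.random(30) * 10
            pos = [call_positive(trace(values), ThresholdSet(sigma=s)).positive
                   for s in (0.5, 1.0, 2.0, 4.0)]
            # once negative at some threshold, stays negative at higher ones
            assert all(a or not b for a, b in zip(pos, pos[1:]))

    def test_short_trace_flagged(self):
        call = call_positive(trace([5.0, 5.0]), self.TH, min_run=3)
        assert not call.positive and call.insufficient_data

    def test_degenerate_sigma_refused(self):
        with pytest.raises(ValueError):
            call_positive(trace(np.ones(10)), ThresholdSet(sigma=0.0, degenerate=True))

    def test_exhaustive_against_oracle_short_patterns(self):
        """All binary patterns up to length 8 match the brute-force rule."""
        for n in range(2, 9):
            for bits in itertools.product([0, 1], repeat=n):
                call = call_positive(trace_from_pattern(bits), self.TH)
                want_pos, want_onset = oracle_positive(bits)
                assert call.positive == want_pos, bits
                assert call.onset_frame == want_onset, bits


class TestClassifyActivity:
    TH = ThresholdSet(sigma=1.0)

    def make_call(self, values):
        return call_positive(trace(values), self.TH)

    def test_silent_when_not_positive(self):
        call = self.make_call(np.zeros(10))
        assert classify_activity(call, self.TH) == "silent"

    def test_hyperactive_above_fifty_sigma(self):
        call = self.make_call([100.0] * 5)
        assert classify_activity(call, self.TH) == "hyperactive"

    def test_slightly_active_between_limits(self):
        call = self.make_call([10.0] * 5)
        assert classify_activity(call, self.TH) == "slightly_active"

    def test_boundary_is_hyperactive(self):
        call = self.make_call([50.0] * 5)
        assert classify_activity(call, self.TH) == "hyperactive"

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(3)
        calls = [self.make_call(rng.random(20) * rng.choice([1, 30, 300]))
                 for _ in range(100)]
        classes = [classify_activity(c, self.TH) for c in calls]
        assert all(c in ("silent", "slightly_active", "hyperactive")
                   for c in classes)
        assert len(classes) == 100

    def test_kmeans_concordance_on_separated_population(self):
        rng = np.random.default_rng(11)
        low = 10 ** rng.normal(1.0, 0.15, 200)    # ~10 sigma
        high = 10 ** rng.normal(2.3, 0.15, 80)    # ~200 sigma
        res = kmeans_concordance(np.concatenate([low, high]), self.TH, seed=0)
        assert res["concordance"] > 0.95
        assert 30 < res["boundary"] < 120


class TestActivationCurve:
    TH = ThresholdSet(sigma=1.0)

    def _call_at(self, onset, n=10):
        v = np.zeros(n)
        if onset is not None:
            v[onset:] = 5.0
        return call_positive(trace(v), self.TH)

    def test_single_step(self):
        calls = [self._call_at(1) for _ in range(20)]
        curve = activation_curve(calls, horizon=10.0)
        assert curve.fraction_activated[-1] == pytest.approx(1.0)
        # the jump happens at t=1
        assert curve.fraction_activated[np.searchsorted(curve.times, 1.0)] == 1.0

    def test_no_onsets_flat_zero(self):
        calls = [self._call_at(None) for _ in range(10)]
        curve = activation_curve(calls, horizon=10.0)
        assert np.all(curve.fraction_activated == 0.0)
        assert np.all(~curve.events)

    def test_exponential_onsets_recovered(self):
        """Empirical activation matches 1 - exp(-lam t) within a binomial CI."""
        rng = np.random.default_rng(21)
        lam, n, horizon = 0.2, 400, 50.0
        onsets = rng.exponential(1 / lam, n)
        calls = []
        for o in onsets:
            f = int(np.ceil(o))
            calls.append(self._call_at(f if f < 40 else None, n=40))
        curve = activation_curve(calls, horizon=horizon)
        t_check = 10.0
        frac = np.interp(t_check, curve.times, curve.fraction_activated)
        expected = 1 - np.exp(-lam * t_check)
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n) + 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            activation_curve([], horizon=10.0)


class TestCompareGroups:
    def test_identical_groups_logrank_zero(self):
        d = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=bool)
        res = compare_groups((d, e), (d, e), method="logrank")[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_bh_step_up_hand_computed(self):
        """p = {0.01, 0.02, 0.03}, m=3 adjusts to {0.03, 0.03, 0.03}."""
        rng = np.random.default_rng(0)
        # build three comparisons whose raw p-values we then overwrite is
        # brittle; instead check the BH arithmetic through statsmodels the
        # way compare_groups applies it
        from statsmodels.stats.multitest import multipletests
        _, p_adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(p_adj, [0.03, 0.03, 0.03])

    def test_family_adjustment_applied(self):
        rng = np.random.default_rng(8)
        fams_a = [rng.normal(0, 1, 50) for _ in range(4)]
        fams_b = [rng.normal(1.5, 1, 50) for _ in range(4)]
        results = compare_groups(fams_a, fams_b, method="mannwhitney")
        assert len(results) == 4
        for r in results:
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_value

    def test_shifted_distributions_detected(self):
        """1-SD shift at n=200/group rejects far below 0.001."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        res = compare_groups(a, b, method="mannwhitney")[0]
        assert res.p_value < 0.001

    def test_all_tied_data_p_one_with_warning(self):
        res = compare_groups(np.ones(10), np.ones(12), method="mannwhitney")[0]
        assert res.p_value == 1.0 and res.tie_warning

    def test_significance_labels(self):
        assert significance_label(0.2) == "ns"
        assert significance_label(0.04) == "*"
        assert significance_label(0.004) == "**"
        assert significance_label(0.0004) == "***"
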