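"""Through-origin regression, duration selection, Bland-Altman and paired tests."""

import itertools

import numpy as np
import pytest

from bendr import (
    RegressionResult,
    bland_altman,
    compare_conditions,
    cross_condition_correlation,
    regress_through_origin,
    select_duration,
)


def _reg(k=1.0, r2=1.0, n=23):
    return RegressionResult(k=k, se_k=0.01, r_squared=r2, pearson_r=1.0, p_value=0.0, n=n)


class TestThroughOriginRegression:
    def test_identity(self):
        x = np.array([0.1, 0.2, 0.35, 0.5])
        res = regress_through_origin(x, x)
        assert res.k == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_exact_half_slope(self):
        x = np.array([0.2, 0.4, 0.6])
        res = regress_through_origin(0.5 * x, x)
        assert res.k == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # k = sum(xy)/sum(x^2) = (1.1 + 3.8 + 9.6)/14 = 14.5/14
        res = regress_through_origin([1.1, 1.9, 3.2], [1.0, 2.0, 3.0])
        assert res.k == pytest.approx(14.5 / 14.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 1.0, 23)
        y = 0.9 * x + rng.normal(0, 0.02, 23)
        base = regress_through_origin(y, x).k
        assert regress_through_origin(3.0 * y, x).k == pytest.approx(3.0 * base)
        assert regress_through_origin(y, 2.0 * x).k == pytest.approx(base / 2.0)

    def test_uncentered_r2_stays_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(0.1, 1.0, 10)
            y = 0.8 * x + rng.normal(0, 0.1, 10)
            res = regress_through_origin(y, x)
            assert 0.0 <= res.r_squared <= 1.0

    def test_centered_convention_available(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.2])
        a = regress_through_origin(y, x, r2_convention="uncentered")
        b = regress_through_origin(y, x, r2_convention="centered")
        assert a.r_squared != b.r_squared

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            regress_through_origin([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="identically zero"):
            regress_through_origin([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])

    def test_planted_slope_recovered_within_three_se(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 0.4, 23)
        y = 0.93 * x + rng.normal(0, 0.01, 23)
        res = regress_through_origin(y, x)
        assert abs(res.k - 0.93) <= 3 * res.se_k


class TestDurationSelection:
    def test_all_windows_qualify_selects_first(self):
        table = {i: _reg() for i in range(12, 72, 2)}
        assert select_duration(table).optimal_I == 12

    def test_planted_smallest_qualifying_window(self):
        table = {
            i: _reg(k=0.97 if i >= 40 else 0.90, r2=0.999) for i in range(12, 72, 2)
        }
        assert select_duration(table).optimal_I == 40

    def test_no_qualifying_slope_gives_absent_flag(self):
        table = {i: _reg(k=0.90) for i in range(12, 72, 2)}
        assert select_duration(table).optimal_I is None

    def test_raising_thresholds_never_selects_smaller_window(self):
        rng = np.random.default_rng(5)
        table = {
            i: _reg(k=float(rng.uniform(0.9, 1.0)), r2=float(rng.uniform(0.98, 1.0)))
            for i in range(12, 72, 2)
        }
        base = select_duration(table).optimal_I
        for r2_thr, k_thr in [(0.992, 0.95), (0.99, 0.96), (0.995, 0.97)]:
            harder = select_duration(
                table, r2_threshold=r2_thr, slope_threshold=k_thr
            ).optimal_I
            if base is not None and harder is not None:
                assert harder >= base

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_duration({})


class TestBlandAltman:
    def test_identical_inputs(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_reference_bias_and_sd_reproduce_published_limits(self):
        # bias -0.0052, SD of differences 0.0105 must give limits
        # (-0.0258, 0.0154) under the 1.96-SD convention
        bias, sd = -0.0052, 0.0105
        c = sd * np.sqrt(3.0) / 2.0  # sample SD of (+c, -c, +c, -c) is 2c/sqrt(3)
        diffs = bias + np.array([c, -c, c, -c])
        res = bland_altman(diffs, np.zeros(4))
        assert res.bias == pytest.approx(bias, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert res.loa_low == pytest.approx(-0.0258, abs=5e-5)
        assert res.loa_high == pytest.approx(0.0154, abs=5e-5)

    def test_alternating_differences_closed_form(self):
        c = 0.3
        n = 10
        d = np.tile([c, -c], n // 2)
        res = bland_altman(d, np.zeros(n))
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        expected = 1.96 * c * np.sqrt(n / (n - 1))
        assert res.loa_high == pytest.approx(expected)
        assert res.loa_low == pytest.approx(-expected)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ab = bland_altman(a, b)
        ba = bland_altman(b, a)
        assert ba.bias == pytest.approx(-ab.bias)
        assert ba.loa_low == pytest.approx(-ab.loa_high)
        assert ba.loa_high == pytest.approx(-ab.loa_low)

    def test_width_is_consistent_with_sd(self):
        rng = np.random.default_rng(4)
        res = bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)
        assert res.loa_low <= res.bias <= res.loa_high


def _wilcoxon_exact_oracle(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = float(ranks[diffs > 0].sum())
    w_mid = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - w_mid) >= abs(w_obs - w_mid) - 1e-12:
            count += 1
    return count / 2.0**n


class TestPairedComparisons:
    def test_identical_samples_paired_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, p = compare_conditions(a, a, test="paired_t")
        assert stat == 0.0
        assert p == 1.0

    def test_wilcoxon_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        box = rng.normal(0.2, 1.0, 10)
        stool = rng.normal(0.0, 1.0, 10)
        _, p = compare_conditions(box, stool, test="wilcoxon")
        assert p == pytest.approx(_wilcoxon_exact_oracle(box - stool), abs=1e-12)

    def test_degenerate_pairs_error(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="degenerate pairs"):
            compare_conditions(a, a, test="wilcoxon")

    def test_minimum_pair_count_enforced(self):
        with pytest.raises(ValueError, match="at least 5"):
            compare_conditions([1.0, 2.0], [2.0, 1.0])

    def test_clear_contrast_is_significant(self):
        rng = np.random.default_rng(11)
        stool = rng.normal(24.0, 3.0, 23)
        box = stool * 1.4 + rng.normal(0, 1.0, 23)
        _, p = compare_conditions(box, stool, test="wilcoxon")
        assert p < 0.05


class TestCrossConditionCorrelation:
    def test_identical_vectors(self):
        x = np.array([0.1, 0.25, 0.3, 0.18])
        r, _ = cross_condition_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_orthogonal_zero_mean_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = cross_condition_correlation(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)
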