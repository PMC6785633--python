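"""Rhythm engine: JTK exact null, Lomb-Scargle, Fisher combination, meta-fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import enumerated_pattern_p, lomb_power_direct
from ladcycle import (
    assign_period_group,
    assign_phase_group,
    cosine_fit,
    fisher_combine,
    jtk_cycle,
    lomb_scargle,
    meta_fit,
    zscore_normalize,
)
from ladcycle.rhythm import _pattern_p


class TestJtk:
    def test_exact_null_matches_enumeration(self, times6):
        """Exact tail of Kendall S equals the full 720-permutation frequency."""
        rng = np.random.default_rng(20)
        for _ in range(3):
            y = rng.normal(size=6)
            for period in (12, 18, 24, 30, 36):
                for lag in range(0, period, 6):
                    ref = np.round(np.cos(2 * np.pi * (times6 - lag) / period), 9)
                    if np.ptp(ref) == 0:
                        continue
                    assert _pattern_p(y, ref) == pytest.approx(
                        enumerated_pattern_p(y, ref), abs=1e-12
                    )

    def test_pure_cosine_recovers_period_and_lag(self, times6):
        y = np.cos(2 * np.pi * times6 / 24)
        fit = jtk_cycle(y, times6)
        assert fit.period == 24.0
        assert fit.lag == 0.0
        # with distinct values, perfect concordance attains the exact
        # minimum two-sided p for the 24 h pattern: 2 * (1!3!2!)/6!
        noisy = y + np.random.default_rng(42).normal(0, 0.01, 6)
        fit2 = jtk_cycle(noisy, times6)
        assert (fit2.period, fit2.lag) == (24.0, 0.0)
        assert fit2.p == pytest.approx(2 / 60)

    def test_constant_series_is_uninformative(self, times6):
        fit = jtk_cycle(np.full(6, 5.0), times6)
        assert fit.p == 1.0 and fit.period is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            jtk_cycle([1.0, 2.0, 3.0], [0.0, 6.0, 12.0])

    def test_tied_data_uses_finite_p(self, times6):
        y = np.array([1.0, 0.0, -1.0, 0.0, 1.0, 0.0])  # ties in data
        fit = jtk_cycle(y, times6)
        assert 0 < fit.p <= 1.0


class TestLombScargle:
    def test_noiseless_recovery_within_grid_step(self, times6):
        fit = lomb_scargle(np.cos(2 * np.pi * times6 / 24), times6)
        assert abs(fit.period - 24) <= 1.0

    def test_constant_series(self, times6):
        assert lomb_scargle(np.full(6, 3.3), times6).p == 1.0

    def test_power_matches_direct_formula(self, times6):
        """scipy-backed periodogram equals the textbook Lomb expression."""
        rng = np.random.default_rng(21)
        y = rng.normal(size=6)
        fit = lomb_scargle(y, times6)
        var = y.var(ddof=1)
        for k in range(0, len(fit.frequencies), 5):
            f = fit.frequencies[k]
            assert fit.power[k] == pytest.approx(lomb_power_direct(y, times6, f) / var, rel=1e-8)

    def test_white_noise_calibration(self, times6):
        """Analytic peak p-value is conservative-to-calibrated on white noise."""
        rng = np.random.default_rng(22)
        n_sim = 1000
        hits = sum(
            lomb_scargle(rng.normal(size=6), times6).p < 0.05 for _ in range(n_sim)
        )
        # empirical P(p < 0.05) must be consistent with a true rate <= 0.10
        assert hits <= stats.binom.ppf(0.995, n_sim, 0.10)


class TestFisher:
    def test_examples(self):
        assert fisher_combine([1.0, 1.0]) == 1.0
        assert fisher_combine([0.5]) == pytest.approx(0.5)
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert fisher_combine([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, 4))

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_combine([0.0, 0.5]) < 1e-100

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=5),
        idx=st.integers(0, 4),
        factor=st.floats(0.01, 0.99),
    )
    def test_monotone_in_each_argument(self, ps, idx, factor):
        """Decreasing any single input p never increases the combined p."""
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = ps[idx] * factor
        assert fisher_combine(smaller) <= fisher_combine(ps) + 1e-12


class TestGrouping:
    @pytest.mark.parametrize(
        "period, group",
        [(13.4, 12), (16.2, 18), (33.5, None), (15.0, 12), (21.0, 18), (24.0, 24),
         (33.0, 30), (8.9, None), (float("nan"), None)],
    )
    def test_period_group(self, period, group):
        assert assign_period_group(period) == group

    @pytest.mark.parametrize(
        "phase, period, expected",
        [(0.0, 24.0, "0"), (12.0, 24.0, "pi"), (6.0, 24.0, "pi/2"), (18.0, 24.0, "-pi/2")],
    )
    def test_phase_group(self, phase, period, expected):
        assert assign_phase_group(phase, period) == expected

    def test_twelve_hour_group_has_no_quadrature(self):
        # a quadrature phase must snap to 0 or pi when the 12 h group applies
        assert assign_phase_group(3.0, 12.0, twelve_h=True) in ("0", "pi")
        assert assign_phase_group(6.0, 12.0, twelve_h=True) == "pi"


class TestZscoreAndCosineFit:
    def test_zscore(self):
        assert np.allclose(zscore_normalize([1, 2, 3]), [-1, 0, 1])
        assert np.allclose(zscore_normalize([4.0] * 6), 0.0)
        z = zscore_normalize(np.random.default_rng(0).normal(size=10))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_cosine_fit_recovers_parameters(self, times6):
        y = 2.0 + 1.5 * np.cos(2 * np.pi * (times6 - 7.0) / 24.0)
        base, amp, phase = cosine_fit(y, times6, 24.0)
        assert base == pytest.approx(2.0, abs=1e-9)
        assert amp == pytest.approx(1.5, abs=1e-9)
        assert phase == pytest.approx(7.0, abs=1e-9)


class TestMetaFit:
    def test_two_replicates_beat_one(self, times6):
        """Fisher combination sharpens equal evidence from two replicates."""
        y = 0.6 + 0.4 * np.cos(2 * np.pi * times6 / 24)
        single = meta_fit(y, times6)
        double = meta_fit(np.vstack([y, y]), times6)
        assert double.period_group == 24
        assert double.p_combined < single.p_combined

    def test_period_mean_is_method_average(self, times6):
        fit = meta_fit(0.6 + 0.4 * np.cos(2 * np.pi * times6 / 24), times6)
        assert fit.period_mean == pytest.approx((fit.period_jtk + fit.period_ls) / 2)

    def test_all_constant_replicates(self, times6):
        fit = meta_fit(np.full((2, 6), 1.0), times6)
        assert fit.p_combined == 1.0
        assert fit.period_group is None and math.isnan(fit.period_mean)

    def test_time_shift_covariance(self, times6):
        """A circular one-step shift moves the phase by dt and keeps p."""
        y = np.cos(2 * np.pi * times6 / 24)
        shifted = np.roll(y, 1)
        a, b = meta_fit(y, times6), meta_fit(shifted, times6)
        assert b.p_combined == pytest.approx(a.p_combined)
        assert (b.phase_h - a.phase_h) % a.period_mean == pytest.approx(
            6.0 % a.period_mean, abs=0.6
        )

    def test_quadrature_blind_12h(self, times6):
        """A 12 h cosine at quadrature sampled every 6 h is flat: no rhythm."""
        y = np.round(np.cos(2 * np.pi * (times6 - 3.0) / 12.0), 12)
        assert np.all(y == 0.0)
        assert meta_fit(np.vstack([y, y]), times6).p_combined == 1.0

    def test_mismatched_grid_rejected(self, times6):
        with pytest.raises(ValueError):
            meta_fit(np.ones((2, 5)), times6)

    def test_strategies_agree_on_strong_signal(self, times6):
        y = 0.6 + 0.4 * np.cos(2 * np.pi * times6 / 18)
        arr = np.vstack([y, y])
        for strategy in ("replicates", "flat"):
            fit = meta_fit(arr, times6, strategy=strategy)
            assert fit.period_group == 18
            assert fit.p_combined < 0.05
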