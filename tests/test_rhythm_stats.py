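"""Rhythmicity measures against naive oracles, closed forms and published bands."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import eclorhythm as er
from eclorhythm.io_formats import DailyProfile
from eclorhythm.rhythm_stats import (
    DegenerateSeriesError,
    classify_ri,
    winfree_R,
)

from conftest import hourly_profile_from_counts


def naive_autocorr(y, max_lag):
    """O(N·L) double-loop biased autocorrelation estimate."""
    y = np.asarray(y, float)
    n = len(y)
    yc = y - y.mean()
    denom = sum(v * v for v in yc)
    out = []
    for k in range(max_lag + 1):
        s = 0.0
        for t in range(n - k):
            s += yc[t] * yc[t + k]
        out.append(s / denom)
    return np.array(out)


def naive_winfree(counts, window=8):
    """Exhaustive search over all 24 circular window starts."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    best_inside, best_start = -1.0, None
    for s in range(24):
        inside = sum(counts[(s + i) % 24] for i in range(window))
        if inside > best_inside:
            best_inside, best_start = inside, s
    return 100.0 * (total - best_inside) / best_inside, best_start


class TestAutocorrelogram:
    def test_cosine_has_peaks_at_24_and_48(self, cosine_profile):
        corr = er.autocorrelogram(cosine_profile, max_lag_hours=60)
        v = corr.values
        for lag in (24, 48):
            assert v[lag] > v[lag - 2] and v[lag] > v[lag + 2]

    def test_cosine_lag48_matches_biased_closed_form(self, cosine_profile):
        # biased estimator of a pure cosine decays as (N-k)/N
        corr = er.autocorrelogram(cosine_profile, max_lag_hours=48)
        assert corr.values[48] == pytest.approx((144 - 48) / 144, abs=0.02)

    def test_matches_double_loop_oracle_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = rng.integers(0, 30, size=80)
            if y.var() == 0:
                continue
            prof = hourly_profile_from_counts(y)
            corr = er.autocorrelogram(prof, max_lag_hours=30)
            np.testing.assert_allclose(
                corr.values, naive_autocorr(y, 30), atol=1e-10
            )

    def test_white_noise_band_coverage_near_95_percent(self):
        rng = np.random.default_rng(1)
        n, inside = 144, 0
        reps = 1000
        for _ in range(reps):
            y = rng.integers(0, 40, size=n)
            corr = er.autocorrelogram(y_profile(y), max_lag_hours=24)
            if abs(corr.values[24]) <= corr.confidence_band:
                inside += 1
        # the 2/sqrt(N) band is conservative at long lags for the biased estimator
        assert inside / reps >= 0.94

    def test_zero_variance_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            er.autocorrelogram(hourly_profile_from_counts(np.full(96, 5)))


def y_profile(y):
    return hourly_profile_from_counts(y)


class TestRhythmicityIndex:
    def test_cosine_ri_matches_oracle(self, cosine_profile):
        corr = er.autocorrelogram(cosine_profile, max_lag_hours=56)
        ri, cls, distinct = er.rhythmicity_index(corr)
        assert distinct
        assert ri == pytest.approx(naive_autocorr(cosine_profile.counts, 56)[48], abs=1e-12)
        assert ri == pytest.approx(0.667, abs=0.02)
        assert cls == "strong"

    @pytest.mark.parametrize(
        "ri,expected",
        [(0.33, "strong"), (-0.12, "arrhythmic"), (0.43, "strong"),
         (0.2, "weak"), (0.06, "arrhythmic"),
         (0.3, "strong"), (0.1, "weak")],  # boundaries sit with the stronger class
    )
    def test_published_band_classification(self, ri, expected):
        assert classify_ri(ri) == expected

    def test_no_distinct_peak_falls_back_to_lag_2tau(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 5, 96)
        corr = er.autocorrelogram(y_profile(y), max_lag_hours=56)
        ri, _, distinct = er.rhythmicity_index(corr)
        if not distinct:
            assert ri == corr.values[48]


class TestLombScargle:
    def test_cosine_peak_at_24h(self, cosine_profile):
        ls = er.lomb_scargle(cosine_profile)
        assert ls.period_hours == pytest.approx(24.0, abs=0.1)
        assert ls.power > 0

    def test_white_noise_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        reps, hits = 1000, 0
        for _ in range(reps):
            y = rng.integers(0, 40, size=120)
            if er.lomb_scargle(y_profile(y)).power > 0:
                hits += 1
        assert 0.025 <= hits / reps <= 0.075  # binomial 95% CI around 5% is 3.7-6.4%

    def test_flat_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            er.lomb_scargle(hourly_profile_from_counts(np.full(96, 3)))

    def test_power_zero_reported_not_raised(self):
        # a series with no 16-32h component: pure high-frequency alternation
        y = np.tile([0, 10], 48)
        ls = er.lomb_scargle(hourly_profile_from_counts(y))
        assert ls.power == 0.0


class TestCosinor:
    def test_noiseless_cosine_recovered_exactly(self):
        t = np.arange(96)
        y = 5 + 3 * np.cos(2 * np.pi * t / 24)
        fit = er.cosinor_fit(y)
        assert fit.mesor == pytest.approx(5, abs=1e-9)
        assert fit.amplitude == pytest.approx(3, abs=1e-9)
        from eclorhythm.circular_stats import circular_difference_hours

        assert circular_difference_hours(fit.acrophase_hours, 0.0) == pytest.approx(0.0, abs=1e-9)
        assert fit.p_zero_amplitude < 1e-12

    def test_acrophase_follows_shift(self):
        t = np.arange(96)
        y = np.round(50 + 30 * np.cos(2 * np.pi * (t - 9) / 24)).astype(int)
        fit = er.cosinor_fit(hourly_profile_from_counts(y))
        assert fit.acrophase_hours == pytest.approx(9.0, abs=0.05)

    def test_constant_series_flagged_degenerate(self):
        fit = er.cosinor_fit(hourly_profile_from_counts(np.full(96, 7)))
        assert fit.degenerate
        assert fit.amplitude == 0.0
        assert fit.p_zero_amplitude == 1.0

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(6)
        reps, hits = 1000, 0
        for _ in range(reps):
            y = rng.integers(0, 40, size=96)
            if er.cosinor_fit(y_profile(y)).p_zero_amplitude < 0.05:
                hits += 1
        assert 0.030 <= hits / reps <= 0.072


class TestWinfreeR:
    def test_all_inside_gate_gives_zero(self):
        counts = np.zeros(24, int)
        counts[6:14] = 5
        r, start, cls = winfree_R(DailyProfile(counts))
        assert r == 0.0 and start == 6 and cls == "strong"

    def test_uniform_profile_gives_200(self):
        r, start, cls = winfree_R(DailyProfile(np.ones(24, int)))
        assert r == pytest.approx(200.0)
        assert start == 0  # tie broken to earliest start
        assert cls == "arrhythmic"

    @pytest.mark.parametrize("r,expected", [(47.3, "strong"), (102.3, "arrhythmic"),
                                            (84.1, "weak"), (60.0, "strong"),
                                            (90.0, "weak"), (117.1, "arrhythmic")])
    def test_published_band_classification(self, r, expected):
        from eclorhythm.rhythm_stats import classify_winfree

        assert classify_winfree(r) == expected

    @given(st.lists(st.integers(0, 50), min_size=24, max_size=24).filter(lambda c: sum(c) > 0))
    def test_matches_exhaustive_oracle(self, counts):
        r, start, _ = winfree_R(DailyProfile(np.array(counts)))
        r_o, start_o = naive_winfree(counts)
        assert r == pytest.approx(r_o)
        assert start == start_o

    @given(st.lists(st.integers(0, 50), min_size=24, max_size=24).filter(lambda c: sum(c) > 0),
           st.integers(1, 23), st.integers(2, 7))
    def test_rotation_and_scaling_invariance(self, counts, shift, scale):
        base = np.array(counts)
        r0, _, _ = winfree_R(DailyProfile(base))
        r_rot, _, _ = winfree_R(DailyProfile(np.roll(base, shift)))
        r_scaled, _, _ = winfree_R(DailyProfile(base * scale))
        assert r_rot == pytest.approx(r0)
        assert r_scaled == pytest.approx(r0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            winfree_R(DailyProfile(np.zeros(24, int)))


class TestMeanInvariance:
    def test_ri_ls_amplitude_invariant_under_constant_offset(self, gated_profile):
        base = gated_profile.counts
        shifted = hourly_profile_from_counts(base + 13)
        corr0 = er.autocorrelogram(gated_profile)
        corr1 = er.autocorrelogram(shifted)
        np.testing.assert_allclose(corr0.values, corr1.values, atol=1e-12)
        assert er.lomb_scargle(shifted).raw_peak == pytest.approx(
            er.lomb_scargle(gated_profile).raw_peak, rel=1e-9
        )
        a0 = er.cosinor_fit(gated_profile).amplitude
        a1 = er.cosinor_fit(shifted).amplitude
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_cosinor_amplitude_scales_linearly(self, gated_profile):
        a0 = er.cosinor_fit(gated_profile).amplitude
        tripled = hourly_profile_from_counts(gated_profile.counts * 3)
        assert er.cosinor_fit(tripled).amplitude == pytest.approx(3 * a0, rel=1e-9)


class TestClassifyExperimentSet:
    def test_seven_of_nine_rhythmic_by_autocorrelation(self):
        reports = [_report(ri=0.2 if i < 7 else 0.05) for i in range(9)]
        tab = er.classify_experiment_set(reports).set_index("method")
        assert tab.loc["autocorrelation", "n_rhythmic"] == 7
        assert tab.loc["autocorrelation", "proportion_rhythmic"] == pytest.approx(7 / 9)

    def test_all_arrhythmic_gives_zero(self):
        reports = [_report(ri=-0.2, ls_power=0.0, cos_p=0.8, winfree_r=150.0)
                   for _ in range(4)]
        tab = er.classify_experiment_set(reports)
        assert (tab["proportion_rhythmic"] == 0).all()

    def test_mixed_fixture_set_matches_hand_count(self):
        rows = [
            _report(ri=0.35, ls_power=2.0, cos_p=0.01, winfree_r=30.0),
            _report(ri=0.15, ls_power=0.0, cos_p=0.20, winfree_r=80.0),
            _report(ri=0.05, ls_power=1.0, cos_p=0.04, winfree_r=95.0),
            _report(ri=-0.1, ls_power=0.0, cos_p=0.90, winfree_r=140.0),
            _report(ri=0.12, ls_power=0.5, cos_p=0.06, winfree_r=88.0),
        ]
        tab = er.classify_experiment_set(rows).set_index("method")
        assert tab["n_rhythmic"].to_dict() == {
            "autocorrelation": 3, "lomb_scargle": 3, "cosinor": 2, "winfree": 3
        }


def _report(ri=0.2, ls_power=1.0, cos_p=0.01, winfree_r=50.0):
    return er.RhythmicityReport(
        experiment_id="x", genotype="wt", ri=ri, ri_class=classify_ri(ri),
        ri_distinct_peak=True, ls_power=ls_power, ls_period_hours=24.0,
        ls_raw_peak=ls_power + 5, cos_mesor=10.0, cos_amplitude=3.0,
        cos_acrophase_hours=9.0, cos_p=cos_p, winfree_r=winfree_r,
        gate_start_hour=6, winfree_class="strong" if winfree_r <= 60 else
        ("weak" if winfree_r <= 90 else "arrhythmic"),
    )
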