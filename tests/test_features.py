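import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ropvitals.features import (DEFAULT_EVENT_RULES, FEATURE_FAMILIES,
                                EventRule, auc_threshold, availability,
                                build_feature_matrix, count_events,
                                daily_mean, daily_skewness, filter_valid,
                                pct_time)
from ropvitals.io import read_feature_matrix, write_feature_matrix

from .conftest import make_trace


class TestFilterValid:
    def test_all_valid_identity(self):
        tr = make_trace([90, 91, 92])
        out = filter_valid(tr)
        assert np.array_equal(out.spo2, tr.spo2)

    def test_all_invalid_empty(self):
        tr = make_trace([90, 91, 92], valid=[0, 0, 0])
        assert len(filter_valid(tr)) == 0

    def test_alternating_keeps_half(self):
        tr = make_trace([90.0] * 1000, valid=[1, 0] * 500)
        out = filter_valid(tr)
        assert len(out) == 500
        assert out.nominal_dt == tr.nominal_dt  # denominator preserved


class TestAvailability:
    def test_fully_valid_two_weeks(self):
        tr = make_trace([93.0] * (14 * 1440))  # 1-min samples, days 1-14
        assert availability(tr, 1, 14) == pytest.approx(1.0)

    def test_inclusion_rule_boundary(self):
        n = 14 * 1440
        valid = np.zeros(n, dtype=bool)
        valid[: int(0.79 * n)] = True
        tr = make_trace([93.0] * n, valid=valid)
        frac = availability(tr, 1, 14)
        assert frac == pytest.approx(0.79, abs=1e-3)
        assert frac < 0.80  # excluded by the 80% availability filter

    def test_half_window_coverage(self):
        tr = make_trace([93.0] * (7 * 1440))  # valid data on days 1-7 only
        assert availability(tr, 1, 14) == pytest.approx(0.5)

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            availability(make_trace([93.0]), 5, 4)


class TestDailyMean:
    def test_sf_ratio_constant(self):
        tr = make_trace([95.0] * 1440, fio2=[0.21] * 1440)
        assert daily_mean(tr, "sf_ratio", 1) == pytest.approx(95 / 0.21)

    def test_constant_signal(self):
        tr = make_trace([88.5] * 10)
        assert daily_mean(tr, "spo2", 1) == pytest.approx(88.5)

    def test_half_day_symmetry(self):
        tr = make_trace([90.0] * 720 + [100.0] * 720)
        assert daily_mean(tr, "spo2", 1) == pytest.approx(95.0)

    def test_no_valid_samples_missing(self):
        tr = make_trace([90.0] * 10, valid=[0] * 10)
        assert np.isnan(daily_mean(tr, "spo2", 1))


class TestDailySkewness:
    def test_symmetric_values_zero(self):
        tr = make_trace([1, 2, 3, 4, 5])
        assert daily_skewness(tr, "spo2", 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_moments(self):
        # m2 = 38/3, m3 = 30, correction (2/3)^{3/2}
        tr = make_trace([1, 2, 9])
        expected = 30 / (38 / 3) ** 1.5 * (2 / 3) ** 1.5
        assert daily_skewness(tr, "spo2", 1) == pytest.approx(expected)
        assert daily_skewness(tr, "spo2", 1) == pytest.approx(0.3622, abs=1e-4)

    def test_matches_bias_adjusted_moment_estimator(self):
        rng = np.random.default_rng(1)
        x = rng.normal(90, 3, 200)
        tr = make_trace(x)
        n = len(x)
        want = stats.skew(x, bias=True) * ((n - 1) / n) ** 1.5
        assert daily_skewness(tr, "spo2", 1) == pytest.approx(want)

    @given(st.lists(st.floats(10, 100), min_size=3, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_negation_flips_sign(self, values):
        tr = make_trace(values)
        neg = make_trace([-v for v in values])
        a = daily_skewness(tr, "spo2", 1)
        b = daily_skewness(neg, "spo2", 1)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(-b, abs=1e-8)

    def test_degenerate_inputs_missing(self):
        assert np.isnan(daily_skewness(make_trace([5, 5]), "spo2", 1))
        assert np.isnan(daily_skewness(make_trace([5, 5, 5, 5]), "spo2", 1))


class TestAucThreshold:
    def test_above_threshold_zero(self):
        tr = make_trace([85.0] * 60)
        assert auc_threshold(tr, "spo2", 1, 80, "below") == 0.0

    def test_rectangle_sum_below(self):
        tr = make_trace([70.0] * 10)  # 10 one-minute samples at 70%
        assert auc_threshold(tr, "spo2", 1, 80, "below") == pytest.approx(100.0)

    def test_rectangle_sum_above(self):
        tr = make_trace([98.0] * 30)
        assert auc_threshold(tr, "spo2", 1, 95, "above") == pytest.approx(90.0)

    def test_unknown_side_error(self):
        with pytest.raises(ValueError):
            auc_threshold(make_trace([90.0]), "spo2", 1, 80, "around")


class TestPctTime:
    def test_all_above(self):
        tr = make_trace([97.0] * 20)
        assert pct_time(tr, "spo2", 1, 95, "above") == 100.0

    def test_strict_inequality_above(self):
        tr = make_trace([95.0] * 20)
        assert pct_time(tr, "spo2", 1, 95, "above") == 0.0

    def test_inclusive_below(self):
        tr = make_trace([80.0] * 20)
        assert pct_time(tr, "spo2", 1, 80, "below") == 100.0

    def test_fractional(self):
        tr = make_trace([70.0] * 3 + [90.0] * 9)
        assert pct_time(tr, "spo2", 1, 80, "below") == pytest.approx(25.0)


class TestCountEvents:
    desat = DEFAULT_EVENT_RULES["n_desaturations"]

    def test_no_events(self):
        tr = make_trace([95.0] * 1440)
        assert count_events(tr, self.desat, 1) == 0

    def test_single_dip(self):
        tr = make_trace([95.0] * 10 + [70.0] * 1 + [95.0] * 10)  # 60-s dip
        assert count_events(tr, self.desat, 1) == 1

    def test_merge_gap_rule(self):
        # 5-s sampling: two 30-s dips separated by 5 s merge at merge_gap=10
        dip = [70.0] * 6
        ok = [95.0] * 20
        tr_close = make_trace(ok + dip + [95.0] + dip + ok, dt=5)
        tr_far = make_trace(ok + dip + [95.0] * 12 + dip + ok, dt=5)
        rule = EventRule("spo2", "below", 80.0, min_duration=10, merge_gap=10)
        assert count_events(tr_close, rule, 1) == 1
        assert count_events(tr_far, rule, 1) == 2

    def test_min_duration_filters_short_runs(self):
        tr = make_trace([95.0] * 20 + [70.0] + [95.0] * 20, dt=5)  # 5-s dip
        assert count_events(tr, self.desat, 1) == 0

    def test_monotone_in_min_duration(self):
        rng = np.random.default_rng(3)
        x = 90 + 12 * np.sin(np.arange(500) / 7) + rng.normal(0, 4, 500)
        tr = make_trace(x, dt=30)
        counts = [count_events(tr, EventRule("spo2", "below", 80, min_duration=d), 1)
                  for d in (0, 30, 60, 120, 300)]
        assert counts == sorted(counts, reverse=True)


class TestFeatureMatrix:
    def hand_trace(self):
        """One day of 1-min samples with exactly known feature values."""
        spo2 = np.full(1440, 93.0)
        spo2[100:105] = 70.0   # one 5-min desaturation
        spo2[200:230] = 97.0   # 30 min above 95
        hr = np.full(1440, 150.0)
        hr[300:302] = 90.0     # one bradycardia (2 min)
        hr[400:403] = 210.0    # one tachycardia (3 min)
        fio2 = np.full(1440, 0.25)
        return make_trace(spo2, hr=hr, fio2=fio2)

    def test_hand_computed_cells(self):
        tr = self.hand_trace()
        m = build_feature_matrix([tr], days=1)
        row = m.loc[(0, 1)]
        n = 1440.0
        assert row["mean_spo2"] == pytest.approx((93 * 1405 + 70 * 5 + 97 * 30) / n)
        assert row["mean_hr"] == pytest.approx((150 * 1435 + 90 * 2 + 210 * 3) / n)
        assert row["mean_fio2"] == pytest.approx(0.25)
        assert row["mean_sf_ratio"] == pytest.approx(row["mean_spo2"] / 0.25)
        assert row["auc_below_80"] == pytest.approx(5 * 10.0)    # 5 min, 10% deep
        assert row["auc_above_95"] == pytest.approx(30 * 2.0)    # 30 min, 2% high
        assert row["pct_time_le_80"] == pytest.approx(100 * 5 / n)
        assert row["pct_time_gt_95"] == pytest.approx(100 * 30 / n)
        assert row["n_desaturations"] == 1
        assert row["n_bradycardia"] == 1
        assert row["n_tachycardia"] == 1
        x = tr.spo2
        d = x - x.mean()
        want_skew = (d**3).mean() / (d**2).mean() ** 1.5 * ((n - 1) / n) ** 1.5
        assert row["skew_spo2"] == pytest.approx(want_skew)

    def test_permuting_samples_within_day_preserves_day_statistics(self):
        tr = self.hand_trace()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tr))
        shuffled = make_trace(tr.spo2[perm], hr=tr.hr[perm], fio2=tr.fio2[perm])
        a = build_feature_matrix([tr], days=1)
        b = build_feature_matrix([shuffled], days=1)
        stats_cols = ["mean_spo2", "mean_hr", "mean_fio2", "mean_sf_ratio",
                      "skew_spo2", "skew_hr", "auc_below_80", "auc_above_95",
                      "pct_time_le_80", "pct_time_gt_95"]
        assert np.allclose(a[stats_cols], b[stats_cols])

    def test_doubling_sample_rate_of_piecewise_constant_trace(self):
        tr = self.hand_trace()
        dense = make_trace(np.repeat(tr.spo2, 2), hr=np.repeat(tr.hr, 2),
                           fio2=np.repeat(tr.fio2, 2), dt=30)
        a = build_feature_matrix([tr], days=1)
        b = build_feature_matrix([dense], days=1)
        # skewness carries an explicit ((n-1)/n)^{3/2} small-sample factor,
        # so doubling n moves it by O(1/n); everything else is exact
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=2e-3, equal_nan=True)
        exact = [c for c in a.columns if not c.startswith("skew")]
        assert np.allclose(a[exact].to_numpy(), b[exact].to_numpy(),
                           rtol=1e-12, equal_nan=True)

    def test_cohort_matrix_invariants(self, small_cohort):
        _, traces = small_cohort
        m = build_feature_matrix(traces)
        assert m.shape == (60 * 30, 13)
        assert list(m.columns) == FEATURE_FAMILIES
        counts = m[["n_desaturations", "n_bradycardia", "n_tachycardia"]]
        assert (counts.dropna() >= 0).all().all()
        assert (m[["auc_below_80", "auc_above_95"]].dropna() >= 0).all().all()
        pct = m[["pct_time_le_80", "pct_time_gt_95"]].dropna()
        assert ((pct >= 0) & (pct <= 100)).all().all()
        assert (pct.sum(axis=1) <= 100 + 1e-9).all()

    def test_hypoxia_area_implies_hypoxia_time(self, small_cohort):
        _, traces = small_cohort
        m = build_feature_matrix(traces).dropna()
        has_area = m["auc_below_80"] > 0
        assert (m.loc[has_area, "pct_time_le_80"] > 0).all()

    def test_all_invalid_day_is_missing_not_zero(self):
        valid = np.ones(2 * 1440, dtype=bool)
        valid[:1440] = False  # day 1 fully invalid
        tr = make_trace([93.0] * (2 * 1440), valid=valid)
        m = build_feature_matrix([tr], days=2)
        assert m.loc[(0, 1)].isna().all()
        assert m.loc[(0, 2), "mean_spo2"] == pytest.approx(93.0)

    def test_infant_without_valid_data_excluded(self):
        good = make_trace([93.0] * 100, infant_id=0)
        bad = make_trace([93.0] * 100, valid=[0] * 100, infant_id=1)
        m = build_feature_matrix([good, bad], days=1)
        assert list(m.index.get_level_values("infant_id").unique()) == [0]

    def test_tidy_round_trip(self, tmp_path, small_cohort):
        _, traces = small_cohort
        m = build_feature_matrix(traces[:5])
        path = tmp_path / "features.csv"
        write_feature_matrix(m, path)
        back = read_feature_matrix(path)
        assert np.allclose(m.to_numpy(), back[m.columns].to_numpy(), equal_nan=True)
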