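import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bhpm
from bhpm.panel import (
    CovariateProfile,
    center_within_location,
    previous_year_average,
    standardize_covariates,
)


def daily(start, values):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx)


class TestPreviousYearAverage:
    def test_constant_series_gives_constant(self):
        s = daily("2000-01-01", np.full(800, 13.0))
        starts = pd.date_range("2001-01-01", periods=6, freq="MS")
        out = previous_year_average(s, starts)
        assert len(out) == 6
        assert all(v == pytest.approx(13.0) for _, v in out)

    def test_mean_of_1_to_365(self):
        s = daily("2000-01-02", np.arange(1.0, 366.0))
        out = previous_year_average(s, [pd.Timestamp("2001-01-01")])
        assert out[0][1] == pytest.approx(183.0)

    def test_matches_brute_force_with_gaps(self):
        g = np.random.default_rng(0)
        vals = np.empty(900)
        vals[0] = 12.0
        for i in range(1, 900):
            vals[i] = 12.0 + 0.8 * (vals[i - 1] - 12.0) + g.normal(0, 1.5)
        s = daily("2000-01-01", vals)
        s = s[g.uniform(size=len(s)) > 0.2]  # 20% missing days
        starts = pd.date_range("2001-02-01", periods=10, freq="MS")
        out = dict(previous_year_average(s, starts, min_coverage=0.5))
        for m in starts:
            window = [
                (d, v)
                for d, v in s.items()
                if m - pd.Timedelta(days=365) <= d <= m - pd.Timedelta(days=1)
            ]
            frac = len(window) / 365.0
            if frac >= 0.5:
                assert out[m] == pytest.approx(np.mean([v for _, v in window]))
            else:
                assert m not in out

    def test_low_coverage_month_dropped(self):
        s = daily("2000-12-01", np.full(31, 10.0))  # only 31 of 365 days
        out = previous_year_average(s, [pd.Timestamp("2001-01-01")], min_coverage=0.5)
        assert out == []

    def test_duplicate_dates_rejected(self):
        s = pd.Series([1.0, 2.0], index=pd.to_datetime(["2000-01-01", "2000-01-01"]))
        with pytest.raises(ValueError):
            previous_year_average(s, [pd.Timestamp("2001-01-01")])

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(st.floats(min_value=-50, max_value=50))
    def test_translation_equivariance(self, c):
        g = np.random.default_rng(1)
        s = daily("2000-01-01", 10.0 + g.normal(0, 2, size=500))
        starts = pd.date_range("2001-01-01", periods=4, freq="MS")
        base = previous_year_average(s, starts)
        shifted = previous_year_average(s + c, starts)
        for (m1, v1), (m2, v2) in zip(base, shifted):
            assert m1 == m2
            assert v2 == pytest.approx(v1 + c, abs=1e-9)


class TestCentering:
    def test_two_point_example(self):
        panel = pd.DataFrame(
            {"location_id": ["a", "a"], "month_index": [1, 2],
             "deaths": [1, 2], "at_risk": [100, 100], "exposure": [10.0, 14.0]}
        )
        out, means = center_within_location(panel)
        assert out["exposure_centered"].tolist() == [-2.0, 2.0]
        assert means["a"] == 12.0

    def test_idempotent_on_centered_data(self):
        panel = pd.DataFrame(
            {"location_id": ["a"] * 3, "month_index": [1, 2, 3],
             "deaths": [0, 1, 0], "at_risk": [50, 50, 50],
             "exposure": [-1.0, 0.0, 1.0]}
        )
        out, means = center_within_location(panel)
        assert out["exposure_centered"].tolist() == [-1.0, 0.0, 1.0]
        assert means["a"] == 0.0

    def test_per_location_mean_zero(self, small_study):
        grp = small_study.panel.groupby("location_id")["exposure_centered"].mean()
        assert np.abs(grp.to_numpy()).max() < 1e-12

    def test_single_record_location_rejected(self):
        panel = pd.DataFrame(
            {"location_id": ["a"], "month_index": [1], "deaths": [0],
             "at_risk": [10], "exposure": [5.0]}
        )
        with pytest.raises(ValueError, match="< 2 records"):
            center_within_location(panel)


def make_profiles(z, w, xb):
    return [
        CovariateProfile(
            location_id=f"l{i}", constituents=z[i].astype(float),
            confounders=w[i].astype(float), exposure_mean=float(xb[i]),
        )
        for i in range(len(xb))
    ]


class TestStandardization:
    def test_two_point_column(self):
        z = np.tile([[1.0] * 6], (2, 1))
        z[:, 0] = [0.0, 2.0]
        z[:, 1:] = [[0, 1, 2, 3, 4], [1, 0, 3, 2, 5]]
        w = np.array([[1, 2, 3, 4, 5], [2, 1, 4, 3, 6]], dtype=float)
        profiles, consts = standardize_covariates(make_profiles(z, w, [10.0, 12.0]))
        # SD of {0, 2} with n-1 denominator is sqrt(2)
        assert profiles[0].constituents_std[0] == pytest.approx(-np.sqrt(0.5))
        assert profiles[1].constituents_std[0] == pytest.approx(np.sqrt(0.5))

    def test_columns_have_mean_zero_sd_one(self, small_study):
        z = np.array([p.constituents_std for p in small_study.profiles])
        w = np.array([p.confounders_std for p in small_study.profiles])
        mat = np.column_stack([z, w])
        assert np.abs(mat.mean(axis=0)).max() < 1e-8
        assert np.abs(mat.std(axis=0, ddof=1) - 1.0).max() < 1e-8

    def test_round_trip_through_constants(self):
        g = np.random.default_rng(5)
        z = g.normal(4, 1, size=(12, 6))
        w = g.normal(0.5, 0.1, size=(12, 5))
        xb = g.normal(13, 2, size=12)
        profiles, consts = standardize_covariates(make_profiles(z, w, xb))
        mu = consts.set_index("column")["mean"]
        sd = consts.set_index("column")["sd"]
        for i, p in enumerate(profiles):
            for k, name in enumerate(bhpm.CONSTITUENTS):
                back = p.constituents_std[k] * sd[name] + mu[name]
                assert back == pytest.approx(z[i, k], abs=1e-10)
                fwd = (z[i, k] - mu[name]) / sd[name]
                assert fwd == pytest.approx(p.constituents_std[k], abs=1e-12)

    def test_constant_column_raises_with_name(self):
        g = np.random.default_rng(6)
        z = g.normal(size=(5, 6))
        w = g.normal(size=(5, 5))
        w[:, 2] = 0.93
        with pytest.raises(ValueError, match="urban"):
            standardize_covariates(make_profiles(z, w, g.normal(13, 2, size=5)))
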