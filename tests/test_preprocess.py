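"""Winsorization, yearly binning, feature filters, fold-internal imputation
and omics normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskcarver.preprocess import (
    ImputationModel,
    apply_impute,
    bin_yearly,
    filter_features,
    filter_protein_outliers,
    fit_impute,
    normalize_metabolites,
    winsorize,
)


def _brute_winsorize(x, lo=1, hi=99):
    """Independent oracle: type-7 quantiles by hand, then clip."""
    v = np.sort(x[~np.isnan(x)])
    out = x.copy()
    for q, bound in ((lo / 100, "lo"), (hi / 100, "hi")):
        h = (len(v) - 1) * q
        lo_i, hi_i = int(np.floor(h)), int(np.ceil(h))
        val = v[lo_i] + (h - lo_i) * (v[hi_i] - v[lo_i])
        if bound == "lo":
            out[out < val] = val
        else:
            out[out > val] = val
    return out


def test_winsorize_matches_brute_force_quantile_clip_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=rng.integers(5, 200))
        np.testing.assert_allclose(winsorize(x), _brute_winsorize(x), rtol=0, atol=1e-12)


def test_winsorize_range_on_1_to_100():
    x = np.arange(1.0, 101.0)
    out = winsorize(x)
    assert out.min() == pytest.approx(1 + 0.01 * 99)   # type-7 1st percentile
    assert out.max() == pytest.approx(1 + 0.99 * 99)


def test_winsorize_constant_vector_is_fixed_point():
    np.testing.assert_array_equal(winsorize(np.array([5.0] * 4)), [5.0] * 4)


def test_winsorize_preserves_missing_entries():
    x = np.array([1.0, np.nan, 50.0, 100.0, np.nan])
    out = winsorize(x)
    assert np.isnan(out[[1, 4]]).all()
    assert not np.isnan(out[[0, 2, 3]]).any()


def test_winsorize_all_missing_raises():
    with pytest.raises(ValueError):
        winsorize(np.array([np.nan, np.nan]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_winsorize_is_idempotent_when_percentiles_hit_order_statistics(seed):
    # with (n-1)/100 integral the 1st/99th percentile ranks land exactly on
    # order statistics and winsorization is an exact fixed point; for other
    # n, type-7 interpolation moves the cutoffs strictly inward on repeat
    x = np.random.default_rng(seed).normal(size=301)
    once = winsorize(x)
    np.testing.assert_allclose(winsorize(once), once, rtol=0, atol=0)


def test_winsorize_repeat_drift_is_below_observation_resolution():
    # for general n the second pass moves only the clipped extremes, by less
    # than the spacing of adjacent order statistics near the cutoffs
    x = np.random.default_rng(12).normal(size=500)
    once, twice = winsorize(x), winsorize(winsorize(x))
    v = np.sort(x)
    assert np.max(np.abs(twice - once)) < np.max(np.diff(v))


def test_winsorize_preserves_order_of_interior_points():
    x = np.random.default_rng(8).normal(size=500)
    out = winsorize(x)
    lo, hi = np.percentile(x, [1, 99])
    interior = (x > lo) & (x < hi)
    np.testing.assert_array_equal(out[interior], x[interior])


def _records(rows):
    return pd.DataFrame(rows, columns=["subject_id", "code", "value", "date"])


def test_bin_yearly_median_and_window_boundaries():
    index_dates = pd.Series({"A": 4000})
    # year -1 bin: dates in (3635, 4000]; the 35 leftover days adjacent to
    # the index date (delta in (0, 35] = 365 - 11*30) are the excluded gap
    rec = _records(
        [
            ("A", "alb", 1.0, 4000 - 36),   # delta 36: inside the 11-month window
            ("A", "alb", 2.0, 4000 - 100),
            ("A", "alb", 3.0, 4000 - 200),
            ("A", "alb", 99.0, 4000 - 35),  # delta 35: inside the excluded gap
            ("A", "alb", 42.0, 4000 - 365), # delta 365: still year -1
        ]
    )
    out = bin_yearly(rec, index_dates, continuous_codes=["alb"])
    # median of {1, 2, 3, 42} = 2.5 (the 99 is inside the excluded month)
    assert out.loc["A", "alb_pre1y"] == pytest.approx(2.5)
    assert np.isnan(out.loc["A", "alb_pre2y"])


def test_bin_yearly_odd_count_median():
    index_dates = pd.Series({"A": 2000})
    rec = _records([("A", "crp", v, 2000 - 100 - 10 * i) for i, v in enumerate([1.0, 2.0, 3.0])])
    out = bin_yearly(rec, index_dates, continuous_codes=["crp"])
    assert out.loc["A", "crp_pre1y"] == 2.0


def test_bin_yearly_medication_flags_by_year():
    index_dates = pd.Series({"A": 4000, "B": 4000})
    rec = _records([("A", "nsaid", 1.0, 4000 - 200), ("B", "nsaid", 1.0, 4000 - 400)])
    out = bin_yearly(rec, index_dates, medication_codes=["nsaid"])
    assert out.loc["A", "nsaid_pre1y"] == 1.0
    assert out.loc["A", "nsaid_pre2y"] == 0.0
    assert out.loc["B", "nsaid_pre1y"] == 0.0
    assert out.loc["B", "nsaid_pre2y"] == 1.0


def test_bin_yearly_medication_counts_event_in_excluded_month():
    # the time-gap exclusion applies to continuous snapshots only: any
    # prescription in the year bin flips the flag
    index_dates = pd.Series({"A": 4000})
    rec = _records([("A", "nsaid", 1.0, 4000 - 10)])
    out = bin_yearly(rec, index_dates, medication_codes=["nsaid"])
    assert out.loc["A", "nsaid_pre1y"] == 1.0


def test_filter_features_missingness_rule():
    rng = np.random.default_rng(1)
    col = rng.normal(size=100)
    col[:51] = np.nan
    table = pd.DataFrame({"bad": col, "good": rng.normal(size=100)})
    filtered, report = filter_features(table, np.arange(100))
    assert list(filtered.columns) == ["good"]
    assert report.excluded[0]["reason"] == "missingness"


def test_filter_features_near_zero_variance_rules():
    n = 200
    rng = np.random.default_rng(2)
    table = pd.DataFrame(
        {
            "constant": np.ones(n),
            "rare": np.r_[np.ones(4), np.zeros(n - 4)],       # ratio 49 > 19, 1% unique
            "balanced": rng.integers(0, 2, n).astype(float),  # ratio ~1: retained
            "cont": rng.normal(size=n),
        }
    )
    filtered, report = filter_features(table, np.arange(n))
    assert set(filtered.columns) == {"balanced", "cont"}
    reasons = {e["feature"]: e["reason"] for e in report.excluded}
    assert reasons == {"constant": "near_zero_variance", "rare": "near_zero_variance"}


def test_filter_decisions_ignore_held_out_rows():
    rng = np.random.default_rng(3)
    table = pd.DataFrame({"x": rng.normal(size=100), "y": rng.normal(size=100)})
    train = np.arange(60)
    _, before = filter_features(table, train)
    perturbed = table.copy()
    perturbed.iloc[60:, :] = np.nan  # wreck only held-out rows
    _, after = filter_features(perturbed, train)
    assert before.excluded == after.excluded


def test_filter_all_excluded_raises():
    table = pd.DataFrame({"c": np.ones(50)})
    with pytest.raises(ValueError):
        filter_features(table, np.arange(50))


def test_impute_median_from_training_rows_only():
    table = pd.DataFrame({"x": [1.0, 2.0, 100.0, np.nan]})
    model = fit_impute(table, [0, 1, 2])
    out = apply_impute(model, table)
    assert out.loc[3, "x"] == 2.0
    assert out.notna().all().all()


def test_impute_models_differ_across_folds_with_different_training_data():
    table = pd.DataFrame({"x": [1.0, 1.0, 9.0, 9.0]})
    m1 = fit_impute(table, [0, 1])
    m2 = fit_impute(table, [2, 3])
    assert m1.medians["x"] != m2.medians["x"]


def test_impute_learned_medians_never_depend_on_test_rows():
    rng = np.random.default_rng(4)
    table = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
    train = np.arange(30)
    base = fit_impute(table, train).medians
    for _ in range(10):
        perturbed = table.copy()
        perturbed.iloc[30:, :] = rng.normal(size=(20, 2)) * 100
        pd.testing.assert_series_equal(fit_impute(perturbed, train).medians, base)


def test_impute_feature_without_training_values_raises():
    table = pd.DataFrame({"x": [np.nan, np.nan, 1.0]})
    with pytest.raises(ValueError):
        fit_impute(table, [0, 1])


def test_metabolite_sqrt_normalization_and_ratio_passthrough():
    table = pd.DataFrame({"conc": [9.0, 4.0], "pct": [0.4, 0.6]})
    out = normalize_metabolites(table, ratio_features=["pct"])
    assert list(out["conc"]) == [3.0, 2.0]
    assert list(out["pct"]) == [0.4, 0.6]


def test_negative_metabolite_concentration_raises():
    with pytest.raises(ValueError):
        normalize_metabolites(pd.DataFrame({"conc": [-1.0]}))


def test_protein_outlier_subjects_removed_by_mean_expression_percentile():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(size=(1000, 20)))
    table.iloc[7] += 50.0  # one extreme-mean subject
    filtered, dropped = filter_protein_outliers(table)
    assert 7 in dropped
    # percentile oracle: exactly the subjects outside [0.2, 99.8] of means
    means = table.mean(axis=1)
    lo, hi = np.percentile(means, [0.2, 99.8])
    expected = set(table.index[(means < lo) | (means > hi)])
    assert set(dropped) == expected
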