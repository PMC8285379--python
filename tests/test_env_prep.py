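from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pfcnet import env_prep, synthetic
from pfcnet.env_prep import PrepConfig, filter_variables, knn_impute, scale_center
from pfcnet.types import EnvironmentTable


def make_env(columns: dict, qualitative=()):
    df = pd.DataFrame(columns)
    df.index = [f"s{i}" for i in range(len(df))]
    quals = list(qualitative)
    quants = [c for c in df.columns if c not in quals]
    for q in quals:
        df[q] = df[q].astype(str)
    return EnvironmentTable(data=df, quantitative=quants, qualitative=quals)


class TestFilterVariables:
    def test_constant_column_removed_as_nzv(self):
        env = make_env({"c": [1.0] * 10, "x": np.arange(10.0)})
        out, report = filter_variables(env)
        assert "c" not in out.data.columns
        assert report.set_index("variable").loc["c", "reason"] == "nzv"

    def test_duplicated_column_drops_exactly_one(self):
        x = np.arange(10.0)
        env = make_env({"a": x, "b": x.copy(), "z": np.cos(x)})
        out, report = filter_variables(env)
        assert {"a", "b"} & set(out.data.columns)  # one survivor
        assert len({"a", "b"} - set(out.data.columns)) == 1
        assert (report["reason"] == "corr").sum() == 1

    def test_higher_mean_correlation_member_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        # a ~ b strongly; a also correlates with helper, b does not
        a = base
        b = base + rng.normal(0, 0.25, 200)
        helper = base + rng.normal(0, 0.5, 200)
        env = make_env({"a": a, "b": b, "helper": helper,
                        "n1": rng.normal(size=200), "n2": rng.normal(size=200)})
        out, report = filter_variables(env, PrepConfig(corr_cut=0.9))
        # brute-force oracle: the pair member with larger mean |r| to others
        corr = env.data.corr().abs()
        np.fill_diagonal(corr.values, 0)
        assert corr.loc["a", "b"] > 0.9
        expected_drop = "a" if corr["a"].mean() >= corr["b"].mean() else "b"
        assert expected_drop not in out.data.columns

    def test_no_high_correlation_pair_remains(self, small_env):
        out, _ = filter_variables(small_env)
        quant = out.data[out.quantitative]
        corr = quant.corr().abs()
        np.fill_diagonal(corr.values, 0)
        assert corr.values.max() <= 0.90 + 1e-12

    def test_qualitative_exempt_from_correlation(self):
        x = np.arange(12.0)
        env = make_env(
            {"a": x, "f": ["u", "v"] * 6}, qualitative=["f"]
        )
        out, _ = filter_variables(env)
        assert "f" in out.data.columns


class TestScaleCenter:
    def test_three_values(self):
        env = make_env({"x": [1.0, 2.0, 3.0]})
        out = scale_center(env)
        assert np.allclose(out.data["x"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        env = make_env({"x": rng.normal(size=30)})
        once = scale_center(env)
        twice = scale_center(once)
        assert np.allclose(once.data["x"], twice.data["x"], atol=1e-12)

    def test_missing_values_ignored_in_statistics(self):
        env = make_env({"x": [1.0, 2.0, 3.0, 6.0, np.nan]})
        out = scale_center(env)
        observed = np.array([1.0, 2.0, 3.0, 6.0])
        expected = (observed - observed.mean()) / observed.std(ddof=1)
        assert np.allclose(out.data["x"].dropna(), expected)
        assert np.isnan(out.data["x"].iloc[4])

    def test_constant_column_is_error(self):
        env = make_env({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            scale_center(env)


class TestKnnImpute:
    def test_complete_table_unchanged(self):
        rng = np.random.default_rng(1)
        env = make_env({"x": rng.normal(size=8), "y": rng.normal(size=8)})
        out = knn_impute(env, k=3)
        assert np.allclose(out.data.values.astype(float), env.data.values.astype(float))

    def test_single_missing_cell_matches_hand_computation(self):
        # 6 samples, 2 variables; s5 missing y -> mean of y over 5 nearest by x
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 0.1])
        y = np.array([10.0, 11.0, 12.0, 13.0, 14.0, np.nan])
        env = make_env({"x": x, "y": y})
        out = knn_impute(env, k=5)
        # all other 5 samples are the only candidates: mean of their y
        assert out.data["y"].iloc[5] == pytest.approx(np.mean(y[:5]))

    def test_nearest_neighbors_selected_by_distance(self):
        # 7 samples; the 5 nearest to s6 (by x) are s0..s4, excluding far s5
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 50.0, 0.5])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 100.0, np.nan])
        env = make_env({"x": x, "y": y})
        out = knn_impute(env, k=5)
        assert out.data["y"].iloc[6] == pytest.approx(np.mean([1, 2, 3, 4, 5.0]))

    def test_zero_distance_twin_included(self):
        x = np.array([1.0, 1.0, 5.0, 9.0, 13.0, 17.0])
        z = np.array([2.0, 2.0, 6.0, 10.0, 14.0, 18.0])
        y = np.array([np.nan, 7.0, 8.0, 9.0, 10.0, 11.0])
        env = make_env({"x": x, "z": z, "y": y})
        out = knn_impute(env, k=2)
        # twin s1 at distance 0 plus s2 next-nearest
        assert out.data["y"].iloc[0] == pytest.approx((7.0 + 8.0) / 2)

    def test_too_few_observations_is_error(self):
        env = make_env({"x": [1.0, 2.0, 3.0], "y": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError, match="fewer than k"):
            knn_impute(env, k=2)

    def test_imputed_values_within_observed_range(self, small_env):
        scaled = scale_center(small_env)
        out = knn_impute(scaled, k=5)
        for v in out.quantitative:
            observed = scaled.data[v].dropna()
            imputed_mask = scaled.data[v].isna()
            if imputed_mask.any():
                vals = out.data.loc[imputed_mask, v]
                assert vals.between(observed.min(), observed.max()).all()
        assert not out.data[out.quantitative].isna().any().any()

    def test_deterministic(self, small_env):
        scaled = scale_center(small_env)
        a = knn_impute(scaled, k=5)
        b = knn_impute(scaled, k=5)
        assert (a.data[a.quantitative].values == b.data[b.quantitative].values).all()


class TestPrepareEnvironment:
    def test_full_chain_output_is_complete_and_standardized(self, small_env):
        out, report = env_prep.prepare_environment(small_env)
        assert not out.data[out.quantitative].isna().any().any()
        # scaling happened before imputation, so means stay near 0
        means = out.data[out.quantitative].mean()
        assert (means.abs() < 0.2).all()
        # planted correlated pairs (r = 0.95, 0.92) trigger removals
        assert (report["reason"] == "corr").sum() >= 2
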