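from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pfcnet import ordination
from pfcnet.ordination import (
    fit_cca,
    group_barycenters,
    ordination_aic,
    permutation_test,
    stepwise_select,
)
from pfcnet.types import EnvironmentTable

from _oracles import cca_eigen_oracle


def random_table(n, m, seed, low=1.0, high=50.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(low, high, size=(n, m)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(m)],
    )


def random_design(Y, k, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(len(Y), k)),
        index=Y.index,
        columns=[f"x{j}" for j in range(k)],
    )


class TestFitCca:
    def test_saturated_model_explains_everything(self):
        Y = random_table(6, 5, 0)
        X = pd.DataFrame(
            np.eye(6)[:, :5], index=Y.index, columns=[f"i{j}" for j in range(5)]
        )
        res = fit_cca(Y, X)
        assert res.constrained_inertia == pytest.approx(res.total_inertia, abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_explicit_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m, k = rng.integers(5, 9), rng.integers(4, 9), rng.integers(1, 4)
        Y = random_table(int(n), int(m), seed)
        X = random_design(Y, int(k), seed + 100)
        res = fit_cca(Y, X)
        eig, total, constrained = cca_eigen_oracle(Y.to_numpy(), X.to_numpy())
        assert res.total_inertia == pytest.approx(total, abs=1e-10)
        assert res.constrained_inertia == pytest.approx(constrained, abs=1e-10)
        assert np.allclose(res.eigenvalues, eig[: len(res.eigenvalues)], atol=1e-8)

    def test_matches_vegan_cca(self, tmp_path):
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        Y = random_table(8, 6, 42)
        X = random_design(Y, 2, 7)
        Y.to_csv(tmp_path / "Y.csv")
        X.to_csv(tmp_path / "X.csv")
        script = tmp_path / "cca.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'Y <- read.csv("{tmp_path}/Y.csv", row.names=1)\n'
            f'X <- read.csv("{tmp_path}/X.csv", row.names=1)\n'
            'm <- cca(Y ~ ., data=X)\n'
            'cat(sprintf("%.15g", c(m$CCA$eig, m$tot.chi)), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        values = [float(v) for v in out.stdout.split()]
        vegan_eig, vegan_total = values[:-1], values[-1]
        res = fit_cca(Y, X)
        assert np.allclose(res.eigenvalues, vegan_eig, atol=1e-8)
        assert res.total_inertia == pytest.approx(vegan_total, abs=1e-8)

    def test_eigenvalue_invariants(self):
        Y = random_table(10, 8, 8)
        X = random_design(Y, 3, 9)
        res = fit_cca(Y, X)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.eigenvalues.sum() == pytest.approx(res.constrained_inertia, rel=1e-10)
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_sample_relabeling_leaves_eigenvalues_unchanged(self):
        Y = random_table(9, 7, 10)
        X = random_design(Y, 2, 11)
        res = fit_cca(Y, X)
        perm = np.random.default_rng(0).permutation(len(Y))
        res_p = fit_cca(Y.iloc[perm], X.iloc[perm])
        assert np.allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-10)

    def test_planted_gradient_dominates_biplot(self):
        rng = np.random.default_rng(13)
        n = 30
        v = np.linspace(-1, 1, n)
        Y = pd.DataFrame(
            np.outer(np.exp(2 * v), np.ones(6)) * rng.uniform(0.5, 1.5, 6)
            + np.outer(np.exp(-2 * v), np.ones(6)) * rng.uniform(0.5, 1.5, 6) * np.arange(6),
            index=[f"s{i}" for i in range(n)],
        )
        X = pd.DataFrame(
            {"v": v, "d1": rng.normal(size=n), "d2": rng.normal(size=n)},
            index=Y.index,
        )
        res = fit_cca(Y, X)
        bp = res.biplot_scores["CCA1"].abs()
        assert bp["v"] == bp.max()

    def test_dependent_columns_dropped_with_warning(self):
        Y = random_table(8, 5, 20)
        X = random_design(Y, 2, 21)
        X["dup"] = X["x0"] * 2.0
        with pytest.warns(UserWarning, match="dependent"):
            res = fit_cca(Y, X)
        assert "dup" in res.dropped_columns

    def test_zero_sum_row_is_error(self):
        Y = random_table(6, 4, 30)
        Y.iloc[2] = 0.0
        with pytest.raises(ValueError, match="s2"):
            fit_cca(Y, random_design(Y, 2, 31))

    def test_axis_orientation_convention(self):
        Y = random_table(10, 6, 33)
        X = random_design(Y, 3, 34)
        res = fit_cca(Y, X)
        for axis in res.biplot_scores.columns:
            col = res.biplot_scores[axis]
            assert col.loc[col.abs().idxmax()] > 0

    def test_barycenter_of_all_features_is_column_mean(self):
        Y = random_table(12, 9, 35)
        X = random_design(Y, 2, 36)
        res = fit_cca(Y, X)
        bary = group_barycenters(
            res.feature_scores, {f: ["all"] for f in res.feature_scores.index},
            min_size=1,
        )[0]
        assert np.allclose(bary.position, res.feature_scores.mean(axis=0), atol=1e-12)


class TestPermutationTest:
    def test_planted_gradient_is_significant(self):
        rng = np.random.default_rng(5)
        n = 24
        v = np.linspace(0, 1, n)
        Y = pd.DataFrame(
            np.outer(1 + 3 * v, np.ones(5)) * rng.uniform(0.8, 1.2, (n, 5)),
            index=[f"s{i}" for i in range(n)],
        )
        Y.iloc[:, 2:] = rng.uniform(0.5, 1.5, (n, 3)) * np.exp(-3 * v)[:, None]
        X = pd.DataFrame({"v": v}, index=Y.index)
        p = permutation_test(Y, X, n_perm=199, seed=1)
        assert p <= 0.005

    def test_zero_permutations_is_error(self):
        Y = random_table(6, 4, 1)
        with pytest.raises(ValueError):
            permutation_test(Y, random_design(Y, 1, 2), n_perm=0)

    def test_minimum_attainable_p(self):
        # with n_perm permutations, the smallest possible p is 1/(n_perm + 1)
        rng = np.random.default_rng(5)
        n = 20
        v = np.linspace(0, 1, n)
        Y = pd.DataFrame(
            np.outer(np.exp(3 * v), [1, 0.1, 0.1])
            + np.outer(np.exp(-3 * v), [0.1, 1, 1]),
            index=[f"s{i}" for i in range(n)],
        )
        X = pd.DataFrame({"v": v}, index=Y.index)
        p = permutation_test(Y, X, n_perm=999, seed=3)
        assert p == pytest.approx(1.0 / 1000.0)


class TestStepwise:
    @pytest.fixture()
    def gradient_env(self):
        rng = np.random.default_rng(14)
        n = 30
        v = np.linspace(-1, 1, n)
        Y = pd.DataFrame(
            np.outer(np.exp(2 * v), np.ones(4)) * rng.uniform(0.5, 1.5, 4)
            + np.outer(np.exp(-2 * v), np.arange(1.0, 5.0)),
            index=[f"s{i}" for i in range(n)],
        )
        data = pd.DataFrame({"driver": v}, index=Y.index)
        for j in range(5):
            data[f"noise{j}"] = rng.normal(size=n)
        env = EnvironmentTable(
            data=data, quantitative=list(data.columns), qualitative=[]
        )
        return Y, env

    def test_driver_is_selected(self, gradient_env):
        Y, env = gradient_env
        chosen = stepwise_select(Y, env)
        assert "driver" in chosen

    def test_converged_set_is_fixed_point(self, gradient_env):
        Y, env = gradient_env
        chosen = stepwise_select(Y, env)
        again = stepwise_select(Y, env, start=chosen)
        assert again == chosen

    def test_empty_model_aic_formula(self, gradient_env):
        Y, env = gradient_env
        aic = ordination_aic(Y, env, [])
        from pfcnet.ordination import _chi_square_setup

        Q, _, _ = _chi_square_setup(Y)
        n = Y.shape[0]
        expected = n * np.log((Q**2).sum() / n) + 2 * (0 + 1)
        assert aic == pytest.approx(expected)


class TestBarycenters:
    def test_single_member(self):
        scores = pd.DataFrame(
            {"CCA1": [0.5], "CCA2": [-1.0]}, index=["f1"]
        )
        out = group_barycenters(scores, {"f1": ["g"]}, min_size=10)
        b = out[0]
        assert b.position == (0.5, -1.0)
        assert b.spread == (0.0, 0.0)
        assert b.below_min_size

    def test_two_member_midpoint(self):
        scores = pd.DataFrame(
            {"CCA1": [0.0, 2.0], "CCA2": [0.0, 2.0]}, index=["f1", "f2"]
        )
        b = group_barycenters(scores, {"f1": ["g"], "f2": ["g"]}, min_size=2)[0]
        assert b.position == (1.0, 1.0)
        assert not b.below_min_size

    def test_unknown_feature_is_error(self):
        scores = pd.DataFrame({"CCA1": [0.0]}, index=["f1"])
        with pytest.raises(ValueError, match="unknown"):
            group_barycenters(scores, {"nope": ["g"]})

    def test_matches_loop_oracle_on_random_groups(self):
        rng = np.random.default_rng(44)
        features = [f"f{i}" for i in range(300)]
        scores = pd.DataFrame(
            rng.normal(size=(300, 2)), index=features, columns=["CCA1", "CCA2"]
        )
        membership = {
            f: [f"g{rng.integers(100)}" for _ in range(rng.integers(1, 3))]
            for f in features
        }
        out = {b.group_id: b for b in group_barycenters(scores, membership)}
        # brute-force loop oracle
        groups: dict[str, list[str]] = {}
        for f, gs in membership.items():
            for g in gs:
                groups.setdefault(g, []).append(f)
        assert set(out) == set(groups)
        for g, members in groups.items():
            pts = np.array([scores.loc[m].to_numpy() for m in members])
            assert np.allclose(out[g].position, pts.mean(axis=0), atol=1e-12)
            expected_sd = pts.std(axis=0, ddof=1) if len(members) > 1 else np.zeros(2)
            assert np.allclose(out[g].spread, expected_sd, atol=1e-12)
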