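"""Statistical machinery against hand-worked and library cross-check oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from emomediate import (
    StatError,
    adjust_pvalues,
    correlation_matrix,
    cronbach_alpha,
    hierarchical_r2,
    partial_spearman,
    spearman,
)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        ranks = sps.rankdata(x)
        assert spearman(x, max(ranks) + 1 - ranks)[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # d^2 = (0,1,1,1,1): rho = 1 - 6*4/(5*24) = 0.8
        rho, p = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)
        # cross-check p against scipy's spearmanr
        sp = sps.spearmanr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho0 = spearman(x, y)[0]
        assert spearman(np.exp(x), y)[0] == pytest.approx(rho0)
        assert spearman(x, y**3 + 5 * y)[0] == pytest.approx(rho0)


def _partial_oracle(x, y, Z):
    """Independent oracle: rank, then solve the residual regression by
    explicit normal equations."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    Z = np.asarray(Z, dtype=float)
    RZ = np.column_stack([sps.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    D = np.column_stack([np.ones(len(x)), RZ])
    G = np.linalg.inv(D.T @ D)
    ex = rx - D @ (G @ (D.T @ rx))
    ey = ry - D @ (G @ (D.T @ ry))
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


class TestPartialSpearman:
    FIXED = {
        "z": np.array([0.2, -1.1, 0.7, 1.9, -0.4, 0.05, -2.2, 1.3]),
        "e1": np.array([0.3, -0.2, 0.5, -0.6, 0.1, 0.4, -0.3, 0.2]),
        "e2": np.array([-0.1, 0.6, -0.4, 0.2, -0.5, 0.3, 0.1, -0.2]),
    }

    def test_empty_covariates_reduce_to_spearman(self):
        x, y = self.FIXED["z"], self.FIXED["e1"]
        assert partial_spearman(x, y, np.empty((8, 0))) == pytest.approx(
            spearman(x, y)
        )

    def test_normal_equations_oracle(self):
        z = self.FIXED["z"]
        x = z + self.FIXED["e1"]
        y = z + self.FIXED["e2"]
        rho, _ = partial_spearman(x, y, z[:, None])
        assert rho == pytest.approx(_partial_oracle(x, y, z[:, None]), abs=1e-12)

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["x", "y", "z"])
        df["x"] += df["z"]
        df["y"] += df["z"]
        res = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        pcol = "p_val" if "p_val" in res.columns else "p-val"
        rho, p = partial_spearman(df["x"], df["y"], df[["z"]].to_numpy())
        assert rho == pytest.approx(float(res["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(res[pcol].iloc[0]), abs=1e-9)

    def test_covariate_equal_to_target_rejected(self):
        z = self.FIXED["z"]
        with pytest.raises(StatError):
            partial_spearman(z + self.FIXED["e1"], z, z[:, None])

    def test_collinear_covariates_rejected(self):
        z = self.FIXED["z"]
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(StatError, match="collinear"):
            partial_spearman(self.FIXED["e1"], self.FIXED["e2"], Z)

    def test_null_rejection_rate_at_most_nominal(self):
        """Jointly independent x, y, Z at n=34: reject at <= ~5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=34)
            y = rng.normal(size=34)
            Z = rng.normal(size=(34, 2))
            _, p = partial_spearman(x, y, Z)
            rejections += p < 0.05
        assert rejections / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestPvalueAdjustment:
    def test_single_p_unchanged(self):
        for method in ("holm", "bonferroni"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_holm_hand_stepdown(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "holm"), [0.03, 0.04, 0.04]
        )

    def test_bonferroni_hand_arithmetic(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bonferroni"), [0.03, 0.06, 0.09]
        )

    def test_statsmodels_cross_check(self):
        multitest = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        for method in ("holm", "bonferroni"):
            _, expected, _, _ = multitest.multipletests(p, method=method)
            np.testing.assert_allclose(adjust_pvalues(p, method), expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), idx=st.integers(0, 9))
    def test_monotone_and_holm_below_bonferroni(self, seed, idx):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=10)
        holm = adjust_pvalues(p, "holm")
        bonf = adjust_pvalues(p, "bonferroni")
        assert np.all(holm <= bonf + 1e-12)
        assert np.all(holm >= p - 1e-12)
        # raising one raw p never lowers any adjusted p
        p2 = p.copy()
        p2[idx] = min(1.0, p2[idx] * 1.5 + 0.01)
        assert np.all(adjust_pvalues(p2, "holm") >= holm - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatError):
            adjust_pvalues([0.5, 1.2], "holm")


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        X = np.column_stack([[1.0, 2, 3, 4]] * 3)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_printed_fixture_formula(self):
        X = np.array([[1.0, 1.1], [2.0, 2.0], [3.0, 3.2]])
        # k/(k-1) * (1 - (var1+var2)/var(sum)), sample variances
        item = X.var(axis=0, ddof=1).sum()
        total = X.sum(axis=1).var(ddof=1)
        assert cronbach_alpha(X) == pytest.approx(2 * (1 - item / total))

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        X = rng.normal(size=(15, 4)) + rng.normal(size=(15, 1))
        expected = pingouin.cronbach_alpha(pd.DataFrame(X))[0]
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-9)

    def test_independent_raters_average_near_zero(self):
        # the null alpha is biased slightly negative at finite n (it is a
        # ratio estimate), so the band is O(1/n) wide rather than exact
        rng = np.random.default_rng(2)
        alphas = [
            cronbach_alpha(rng.normal(size=(30, 4))) for _ in range(1000)
        ]
        assert abs(float(np.mean(alphas))) < 0.1

    def test_zero_total_variance_rejected(self):
        with pytest.raises(StatError):
            cronbach_alpha(np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]]))


class TestHierarchicalR2:
    def test_response_equal_to_first_factor(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "v"])
        part = hierarchical_r2(f, f["a"], first="a")
        assert part.r2_first == pytest.approx(1.0)
        assert part.r2_increment == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_response_r2_zero(self):
        rng = np.random.default_rng(1)
        F = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        D = np.column_stack([np.ones(20), F])
        y_resid = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        part = hierarchical_r2(
            pd.DataFrame(F, columns=["a", "v"]), y_resid, first="a"
        )
        assert part.r2_total == pytest.approx(0.0, abs=1e-10)

    def test_six_point_normal_equations_oracle(self):
        F = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5, 6], "v": [2.0, 1, 4, 3, 6, 5]}
        )
        y = np.array([1.5, 2.2, 2.9, 4.4, 4.8, 6.1])

        def oracle_r2(X):
            D = np.column_stack([np.ones(6), X])
            beta = np.linalg.inv(D.T @ D) @ D.T @ y
            resid = y - D @ beta
            return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)

        part = hierarchical_r2(F, y, first="a")
        assert part.r2_first == pytest.approx(oracle_r2(F[["a"]].to_numpy()))
        assert part.r2_total == pytest.approx(oracle_r2(F.to_numpy()))

    def test_total_r2_is_order_invariant_but_increments_are_not(self):
        rng = np.random.default_rng(5)
        F = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "v"])
        y = 2 * F["a"] + 0.5 * F["v"] + rng.normal(size=30)
        p1 = hierarchical_r2(F, y, first="a")
        p2 = hierarchical_r2(F, y, first="v")
        assert p1.r2_total == pytest.approx(p2.r2_total)
        assert p1.r2_first != pytest.approx(p2.r2_first)

    def test_collinear_predictors_rejected(self):
        F = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "v": [2.0, 4, 6, 8, 10]})
        with pytest.raises(StatError, match="collinear"):
            hierarchical_r2(F, [1.0, 2, 1, 2, 1], first="a")


class TestCorrelationMatrix:
    def test_single_pair(self):
        x = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        rep = correlation_matrix(x, x.rename(columns={"x": "y"}))
        assert len(rep.entries) == 1
        assert rep.entries[0].rho == pytest.approx(1.0)

    def test_family_shape_matches_feature_by_dimension_grid(self, mediated_bundle,
                                                            default_config):
        from emomediate.pipeline import run_feature_pmca_analysis

        rep = run_feature_pmca_analysis(mediated_bundle, default_config)
        assert len(rep.entries) == 15 * 4
        df = rep.to_frame()
        assert df["x"].nunique() == 15 and df["y"].nunique() == 4

    def test_adjusted_never_below_raw(self, mediated_bundle, default_config):
        from emomediate.pipeline import run_emotion_pmca_analysis

        df = run_emotion_pmca_analysis(mediated_bundle, default_config).to_frame()
        assert (df.p_adjusted >= df.p_raw - 1e-12).all()
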