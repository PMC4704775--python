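"""Orthogonalization/reduction and the statistical validation battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vfmdi.exceptions import EvaluationError, ScalingError
from vfmdi.feature_space import (
    accumulate_fp,
    anova_per_feature,
    kw_per_feature,
    manova,
    orthogonalize,
    reduce,
)


def _matrix(X, y):
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    df["outcome"] = y
    return df


class TestOrthogonalize:
    def test_projected_columns_uncorrelated_and_variance_preserved(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 12)) @ rng.standard_normal((12, 12))
        m = _matrix(X, rng.integers(0, 2, 50))
        proj, scores = orthogonalize(m, standardize=False)
        Z = scores.drop(columns="outcome").to_numpy()
        C = np.corrcoef(Z, rowvar=False)
        assert np.max(np.abs(C - np.eye(12))) < 1e-8
        assert proj.eigenvalues.sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), abs=1e-9)

    def test_rank_one_data_single_eigenvalue(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((30, 1))
        X = u @ np.array([[1.0, 2.0, -1.0]])
        proj, _ = orthogonalize(_matrix(X, rng.integers(0, 2, 30)), standardize=False)
        assert np.sum(proj.eigenvalues > 1e-12) == 1

    def test_orthogonal_input_eigenvalues_are_column_variances(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([3.0 * rng.standard_normal(200),
                             1.0 * rng.standard_normal(200),
                             0.3 * rng.standard_normal(200)])
        proj, _ = orthogonalize(_matrix(X, rng.integers(0, 2, 200)), standardize=False)
        np.testing.assert_allclose(
            proj.eigenvalues, np.sort(X.var(axis=0, ddof=1))[::-1], rtol=0.2)

    def test_constant_column_scaling_error_names_column(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ScalingError, match="x0"):
            orthogonalize(_matrix(X, np.r_[np.zeros(10, int), np.ones(10, int)]))


class TestReduce:
    def test_threshold_one_keeps_all_nonzero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        proj, scores = orthogonalize(_matrix(X, rng.integers(0, 2, 40)))
        red = reduce(proj, scores, 1.0)
        assert red.shape[1] - 1 == 5

    def test_cumulative_sum_cutoff(self):
        from vfmdi.feature_space import Projection

        proj = Projection(np.zeros(3), None, np.eye(3),
                          np.array([98.0, 1.5, 0.5]), ["a", "b", "c"])
        assert proj.retained(0.99) == 2

    def test_retained_variance_at_default_threshold(self, cohort_features):
        _, feats = cohort_features
        proj, scores = orthogonalize(feats.static_matrix)
        red = reduce(proj, scores, 0.99)
        k = red.shape[1] - 1
        total = proj.eigenvalues.sum()
        assert proj.eigenvalues[:k].sum() / total >= 0.99
        # independent recomputation from the projected scores themselves
        Z = scores.drop(columns="outcome").to_numpy()
        frac = Z[:, :k].var(axis=0, ddof=1).sum() / Z.var(axis=0, ddof=1).sum()
        assert frac >= 0.99


class TestAnova:
    def test_equal_groups_f_near_zero(self):
        X = np.r_[np.arange(10.0), np.arange(10.0)][:, None]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        out = anova_per_feature(_matrix(X, y))
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_between_within_ratio(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        out = anova_per_feature(_matrix(np.r_[a, b][:, None],
                                        np.r_[np.zeros(3, int), np.ones(3, int)]))
        grand = np.r_[a, b].mean()
        ssb = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 4)
        assert out["F"].iloc[0] == pytest.approx(f_oracle, rel=1e-12)

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        y = np.r_[np.zeros(14, int), np.ones(16, int)]
        out = anova_per_feature(_matrix(X, y))
        for j in range(4):
            t, _ = stats.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True)
            assert out["F"].iloc[j] == pytest.approx(t**2, rel=1e-9)

    def test_single_class_rejected(self):
        X = np.arange(8.0)[:, None]
        with pytest.raises(EvaluationError):
            anova_per_feature(_matrix(X, np.zeros(8, int)))


class TestKruskalWallis:
    def test_rank_formula_oracle(self):
        out = kw_per_feature(_matrix(np.array([1.0, 2.0, 3.0, 4.0])[:, None],
                                     np.array([0, 0, 1, 1])))
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        h_oracle = 12 / (4 * 5) * (2 * (1.5 - 2.5) ** 2 + 2 * (3.5 - 2.5) ** 2)
        assert out["H"].iloc[0] == pytest.approx(h_oracle, rel=1e-12)

    def test_identical_groups(self):
        X = np.r_[np.ones(5), np.ones(5)][:, None]
        out = kw_per_feature(_matrix(X, np.r_[np.zeros(5, int), np.ones(5, int)]))
        assert out["H"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        h1 = kw_per_feature(_matrix(X, y))["H"]
        h2 = kw_per_feature(_matrix(np.exp(X), y))["H"]
        np.testing.assert_allclose(h1, h2, rtol=1e-12)


class TestManova:
    def test_equal_mean_vectors(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 4))
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        out = manova(_matrix(X, y))
        assert out["p"] > 0.05

    def test_one_dimension_reduces_to_anova(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 1))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        f_manova = manova(_matrix(X, y))["F"]
        f_anova = anova_per_feature(_matrix(X, y))["F"].iloc[0]
        assert f_manova == pytest.approx(f_anova, rel=1e-9)

    def test_power_on_shifted_means(self):
        # 1 SD shift in 3 of 5 dimensions, n = 200: detected essentially always
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            X = rng.standard_normal((200, 5))
            y = np.r_[np.zeros(100, int), np.ones(100, int)]
            X[y == 1, :3] += 1.0
            if manova(_matrix(X, y))["p"] < 0.05:
                hits += 1
        assert hits >= 0.95 * 200

    def test_statsmodels_cross_check(self):
        # independent route: statsmodels MANOVA (Hotelling-Lawley trace F)
        from statsmodels.multivariate.manova import MANOVA as SmManova

        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 3))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X[y == 1] += 0.4
        ours = manova(_matrix(X, y))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["g"] = y
        res = SmManova.from_formula("a + b + c ~ g", data=df).mv_test()
        table = res.results["g"]["stat"]
        f_sm = float(table.loc["Hotelling-Lawley trace", "F Value"])
        p_sm = float(table.loc["Hotelling-Lawley trace", "Pr > F"])
        assert ours["F"] == pytest.approx(f_sm, rel=1e-6)
        assert ours["p"] == pytest.approx(p_sm, rel=1e-6, abs=1e-12)


class TestAccumulateFp:
    def test_zero_p_values_flat_zero(self):
        out = accumulate_fp(np.zeros(80))
        assert np.all(out["p_fp"] == 0.0)

    def test_single_p(self):
        out = accumulate_fp([0.05])
        assert out["p_fp"].iloc[0] == pytest.approx(0.05)
        assert out["p_fp_scaled"].iloc[0] == pytest.approx(0.5)

    def test_two_p_closed_form(self):
        out = accumulate_fp([0.01, 0.02])
        assert out["p_fp"].iloc[-1] == pytest.approx(1 - 0.99 * 0.98, rel=1e-12)

    def test_batches_of_forty(self):
        out = accumulate_fp(np.full(100, 0.01), batch=40)
        assert list(out["n_features"]) == [40, 80, 100]


def test_type_one_error_calibration_on_permuted_labels(cohort_features):
    """Per-feature ANOVA p < .05 fraction matches its nominal rate under
    label permutation (binomial 99% CI).

    One feature is tested per permutation (rotating through the feature
    set) so the pooled rejections are independent Bernoulli trials and the
    binomial interval is the correct yardstick.
    """
    _, feats = cohort_features
    X = feats.static_matrix.drop(columns="outcome")
    cols = list(X.columns)
    rng = np.random.default_rng(10)
    y = feats.static_matrix["outcome"].to_numpy()
    hits, total = 0, 1000
    for i in range(total):
        m = X[[cols[i % len(cols)]]].copy()
        m["outcome"] = rng.permutation(y)
        hits += int(anova_per_feature(m)["p"].iloc[0] < 0.05)
    frac = hits / total
    ci = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert abs(frac - 0.05) <= ci


def test_validation_report_structure(cohort_features):
    from vfmdi.feature_space import validation_report

    _, feats = cohort_features
    per_feature, summary = validation_report(feats.static_matrix)
    assert {"feature", "F", "p_anova", "H", "p_kw"} <= set(per_feature.columns)
    assert len(per_feature) == feats.static_matrix.shape[1] - 1
    assert 0 <= summary["p_manova"] <= 1
    assert 0 < summary["retained_components"] <= len(per_feature)
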