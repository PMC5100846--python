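"""Model building: OLS, screening, stepwise selection, ANOVA, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaykit import PredictorTable
from decaykit.regression_model import (
    CategoricalAnnotation,
    aic_reduce,
    annotation_indicators,
    backward_stepwise,
    categorical_anova,
    fit_ols,
    forward_stepwise,
    model_plus_plus,
    nested_f_test,
    rank_sum_compare,
    residual_outliers,
    univariate_screen,
    variance_summary,
)
from .conftest import make_linear_table


def _table_from_arrays(X, y, names=None):
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    genes = [f"g{i}" for i in range(n)]
    y = np.asarray(y, dtype=float)
    y = y - min(0.0, y.min()) + 0.01
    return PredictorTable(pd.DataFrame(X, columns=names, index=genes),
                          pd.Series(y, index=genes, name="k_deg"))


class TestFitOls:
    def test_exact_line(self):
        x = np.arange(1.0, 11.0)
        table = _table_from_arrays(x[:, None], 2 * x)
        m = fit_ols(table, ["x0"])
        assert m.coefficients["x0"] == pytest.approx(2.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_null_predictor(self):
        rng = np.random.default_rng(99)
        table = _table_from_arrays(rng.standard_normal((1000, 1)),
                                   rng.standard_normal(1000))
        m = fit_ols(table, ["x0"])
        assert m.r_squared < 0.01
        assert m.p_values["x0"] > 0.05

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            X = rng.standard_normal((40, 3))
            y = rng.standard_normal(40)
            table = _table_from_arrays(X, y)
            m = fit_ols(table, ["x0", "x1", "x2"])
            design = np.column_stack([np.ones(40), X])
            beta = np.linalg.solve(design.T @ design, design.T @ table.response.to_numpy())
            assert m.coefficients.to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        table = _table_from_arrays(np.column_stack([x, 2 * x]), rng.standard_normal(50))
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(table, ["x0", "x1"])

    def test_complete_case_rows(self):
        table = make_linear_table(0, n=50)
        data = table.data.copy()
        data.iloc[:5, 0] = np.nan
        table = PredictorTable(data, table.response)
        m = fit_ols(table, ["x0"])
        assert m.n_used == 45

    def test_insufficient_rows(self):
        table = make_linear_table(0, n=300).subset([f"g{i}" for i in range(3)])
        with pytest.raises(ValueError, match="insufficient"):
            fit_ols(table, ["x0", "x1"])


class TestUnivariateScreen:
    def test_separates_signal_from_noise(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        X = np.column_stack([x, rng.standard_normal(200)])
        table = _table_from_arrays(X, 3 * x, names=["signal", "noise"])
        screen = univariate_screen(table)
        assert screen[0].predictor == "signal"
        assert screen[0].r_squared == pytest.approx(1.0)
        assert screen[0].sign == "+"

    def test_duplicated_column_identical_results(self):
        table = make_linear_table(5, n=200, p=1, n_true=1)
        data = table.data.copy()
        data["x_copy"] = data["x0"]
        table = PredictorTable(data, table.response)
        screen = {r.predictor: r for r in univariate_screen(table)}
        assert screen["x0"].r_squared == pytest.approx(screen["x_copy"].r_squared)
        assert screen["x0"].p_value == pytest.approx(screen["x_copy"].p_value)

    def test_r2_equals_squared_pearson(self):
        table = make_linear_table(6, n=300, p=2)
        for res in univariate_screen(table):
            r, _ = stats.pearsonr(table.data[res.predictor], table.response)
            assert res.r_squared == pytest.approx(r**2, abs=1e-10)


class TestStepwise:
    def test_backward_recovers_true_predictor(self):
        table = make_linear_table(7, n=2000, p=4, n_true=1, beta=1.0)
        m = backward_stepwise(table)
        assert m.terms == ("x0",)

    def test_backward_keeps_orthogonal_significant(self):
        table = make_linear_table(8, n=2000, p=3, n_true=3, beta=0.5)
        m = backward_stepwise(table)
        assert set(m.terms) == {"x0", "x1", "x2"}
        assert m.selection_log == []

    def test_forward_agrees_with_backward(self):
        table = make_linear_table(9, n=2000, p=4, n_true=2, beta=0.5)
        fwd = forward_stepwise(table)
        bwd = backward_stepwise(table)
        assert set(fwd.terms) == set(bwd.terms) == {"x0", "x1"}

    def test_forward_collinear_pair_keeps_one(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        X = np.column_stack([x, x + rng.normal(0, 0.01, 1000)])
        y = x + rng.normal(0, 1.0, 1000)
        table = _table_from_arrays(X, y, names=["a", "b"])
        m = forward_stepwise(table)
        assert len(m.terms) == 1

    def test_forward_single_candidate_equals_fit(self):
        table = make_linear_table(11, n=500, p=1, n_true=1)
        fwd = forward_stepwise(table)
        direct = fit_ols(table, ["x0"])
        assert fwd.terms == ("x0",)
        assert fwd.r_squared == pytest.approx(direct.r_squared)

    def test_no_candidates_raises(self):
        rng = np.random.default_rng(12)
        table = _table_from_arrays(rng.standard_normal((100, 2)),
                                   rng.standard_normal(100))
        screen = univariate_screen(table)
        if all(r.p_value >= 0.05 for r in screen):
            with pytest.raises(ValueError, match="screening"):
                backward_stepwise(table)
        else:  # seed-dependent fallback: force an empty candidate set
            with pytest.raises(ValueError):
                backward_stepwise(table, candidates=[])


class TestAicReduce:
    def test_drops_pure_noise_term(self):
        table = make_linear_table(13, n=2000, p=3, n_true=1, beta=1.0)
        m = aic_reduce(table, ["x0", "x1", "x2"])
        assert "x0" in m.terms and len(m.terms) < 3

    def test_final_aic_never_above_start(self):
        table = make_linear_table(14, n=500, p=4, n_true=2)
        start = fit_ols(table, table.predictors)
        reduced = aic_reduce(table, table.predictors)
        assert reduced.aic <= start.aic

    def test_exact_fit_keeps_all_terms(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((50, 2))
        y = X @ np.array([1.0, -2.0]) + 5
        table = _table_from_arrays(X, y)
        m = aic_reduce(table, ["x0", "x1"])
        assert set(m.terms) == {"x0", "x1"}


class TestCategoricalAnova:
    def test_perfect_separation(self):
        y = pd.Series([1.0] * 5 + [2.0] * 5)
        g = pd.Series(["a"] * 5 + ["b"] * 5)
        r2, p = categorical_anova(y, g)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_null_permutation_r2(self):
        rng = np.random.default_rng(16)
        n, k = 2000, 5
        y = pd.Series(rng.standard_normal(n))
        g = pd.Series(rng.choice([f"c{i}" for i in range(k)], size=n))
        r2, p = categorical_anova(y, g)
        # E[R^2] under the null is (k-1)/(n-1)
        assert r2 == pytest.approx((k - 1) / (n - 1), abs=0.005)

    def test_matches_onehot_ols(self):
        rng = np.random.default_rng(17)
        n = 300
        g = pd.Series(rng.choice(["a", "b", "c"], size=n))
        y = pd.Series(rng.standard_normal(n) + (g == "a") * 0.5)
        r2, p = categorical_anova(y, g)
        X = pd.get_dummies(g, drop_first=True).astype(float).to_numpy()
        table = _table_from_arrays(X, y.to_numpy(), names=["b", "c"])
        m = fit_ols(table, ["b", "c"])
        assert r2 == pytest.approx(m.r_squared, abs=1e-10)

    def test_single_category_raises(self):
        with pytest.raises(ValueError):
            categorical_anova(pd.Series([1.0, 2, 3]), pd.Series(["a", "a", "a"]))


class TestModelPlusPlus:
    @staticmethod
    def _annotations(table, rng, n_terms=3, prevalence=0.2, shift_term=None, shift=0.0):
        annotations = []
        response = table.response.copy()
        for g in table.genes:
            terms = frozenset(
                f"t{j}" for j in range(n_terms) if rng.random() < prevalence
            )
            if shift_term in terms:
                response.loc[g] += shift
            annotations.append(CategoricalAnnotation(g, go_slim_terms=terms))
        return annotations, table.with_response(response)

    def test_r2_never_decreases(self):
        rng = np.random.default_rng(18)
        table = make_linear_table(18, n=800)
        annotations, table = self._annotations(table, rng)
        reduced = fit_ols(table, ["x0", "x1"])
        pp = model_plus_plus(table, reduced, annotations)
        assert pp.n_used == reduced.n_used
        assert pp.r_squared >= reduced.r_squared

    def test_constructed_effect_detected(self):
        rng = np.random.default_rng(19)
        table = make_linear_table(19, n=2000)
        annotations, table = self._annotations(
            table, rng, shift_term="t0", shift=1.0
        )
        reduced = fit_ols(table, ["x0", "x1"])
        pp = model_plus_plus(table, reduced, annotations)
        assert "go:t0" in pp.terms
        assert pp.p_values["go:t0"] < 1e-6

    def test_no_annotations_is_noop(self):
        table = make_linear_table(20, n=300)
        reduced = fit_ols(table, ["x0"])
        pp = model_plus_plus(table, reduced, [])
        assert pp.terms == reduced.terms
        assert pp.r_squared == reduced.r_squared

    def test_prevalence_threshold(self):
        table = make_linear_table(21, n=300)
        annotations = [
            CategoricalAnnotation(g, go_slim_terms=frozenset(["rare"]))
            for g in table.genes[:5]
        ]
        indicators = annotation_indicators(annotations, table.genes, min_prevalence=10)
        assert indicators.shape[1] == 0


class TestNestedFTest:
    def test_null_block_p_uniformish(self):
        rng = np.random.default_rng(22)
        table = make_linear_table(22, n=500)
        reduced = fit_ols(table, ["x0"])
        full = fit_ols(table, ["x0", "x2", "x3"])  # extra null terms
        f, p = nested_f_test(full, reduced)
        assert 0 <= p <= 1

    def test_zero_extra_df(self):
        table = make_linear_table(23, n=200)
        m = fit_ols(table, ["x0"])
        assert nested_f_test(m, m) == (0.0, 1.0)


class TestRankSum:
    def test_exact_enumeration_small_groups(self):
        _, p = rank_sum_compare([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        rng = np.random.default_rng(24)
        a = rng.standard_normal(30)
        _, p = rank_sum_compare(a, a)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_label_symmetry(self):
        rng = np.random.default_rng(25)
        a, b = rng.standard_normal(15), rng.standard_normal(20) + 0.5
        _, p_ab = rank_sum_compare(a, b)
        _, p_ba = rank_sum_compare(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1.0])


class TestResidualOutliers:
    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(26)
        table = make_linear_table(26, n=10_000, p=1, n_true=1, beta=0.5)
        m = fit_ols(table, ["x0"])
        report = residual_outliers(m, table)
        # one-sided 2-SD tail of a normal: ~2.3%
        assert 0.015 <= report.fraction <= 0.032

    def test_zero_variance_residuals(self):
        rng = np.random.default_rng(27)
        X = rng.standard_normal((50, 1))
        table = _table_from_arrays(X, 2 * X[:, 0] + 3)
        m = fit_ols(table, ["x0"])
        report = residual_outliers(m, table)
        assert len(report.genes) == 0

    def test_summary_contrasts_features(self):
        table = make_linear_table(28, n=500)
        m = fit_ols(table, ["x0"])
        report = residual_outliers(m, table)
        assert set(report.summary.columns) == {"outlier_median", "rest_median"}
        assert set(report.summary.index) == set(table.predictors)


class TestVarianceSummary:
    def test_structure_and_nesting(self):
        rng = np.random.default_rng(29)
        table = make_linear_table(29, n=800, p=3, n_true=2)
        screen = univariate_screen(table)
        m = backward_stepwise(table)
        annotations = [
            CategoricalAnnotation(g, go_slim_terms=frozenset(["t"] if rng.random() < 0.3 else []))
            for g in table.genes
        ]
        pp = model_plus_plus(table, m, annotations)
        report = variance_summary(screen, m, pp, table.response)
        assert len(report.table) == len(screen) + 2
        model_rows = report.table.set_index("term")
        assert model_rows.loc["model++", "r_squared"] >= model_rows.loc["model", "r_squared"]
        assert len(report.scatter) == pp.n_used

    def test_perfect_single_predictor_saturates(self):
        x = np.linspace(1, 10, 50)
        table = _table_from_arrays(x[:, None], 2 * x)
        screen = univariate_screen(table)
        m = fit_ols(table, ["x0"])
        report = variance_summary(screen, m, m, table.response)
        assert np.allclose(report.table["r_squared"], 1.0)
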