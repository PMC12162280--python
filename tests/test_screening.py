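import math

import numpy as np
import pandas as pd
import pytest

from mksvrb.cohort import Cohort, ColumnSpec
from mksvrb.screening import (
    SeparationError,
    collinearity_filter,
    compare_groups,
    logistic_fit,
    multivariate_select,
    univariate_screen,
)
from mksvrb.simulate import GeneratorConfig, generate_cohort


def _cat_values(table):
    """Expand a 2x2 table [[a,b],[c,d]] into (values, groups) vectors."""
    values, groups = [], []
    for level, (n_pos, n_neg) in zip("AB", table):
        values += [level] * (n_pos + n_neg)
        groups += [1] * n_pos + [-1] * n_neg
    return np.array(values, dtype=object), np.array(groups)


class TestCompareGroups:
    def test_perfect_independence_gives_zero_chi2(self):
        values, groups = _cat_values([[10, 10], [10, 10]])
        res = compare_groups(values, groups, "categorical")
        assert res.test_used == "chi_square"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_uncorrected_pearson_chi2_hand_value(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*(400-100)^2/(30*30*30*30) = 6.667
        values, groups = _cat_values([[20, 10], [10, 20]])
        res = compare_groups(values, groups, "categorical")
        assert res.statistic == pytest.approx(6.667, abs=5e-4)

    def test_yates_correction_lowers_statistic(self):
        values, groups = _cat_values([[20, 10], [10, 20]])
        plain = compare_groups(values, groups, "categorical")
        yates = compare_groups(values, groups, "categorical", yates=True)
        assert yates.statistic < plain.statistic

    def test_tiny_groups_fall_back_to_mann_whitney(self):
        # 4 cross pairs, all y above x: U for x = 0
        res = compare_groups(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, -1, -1]), "continuous"
        )
        assert res.test_used == "mann_whitney"
        assert res.statistic == 0.0

    def test_normal_data_takes_t_test(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.standard_normal(40) + 0.5, rng.standard_normal(40)])
        groups = np.array([1] * 40 + [-1] * 40)
        assert compare_groups(values, groups, "continuous").test_used == "t_test"

    def test_skewed_data_takes_mann_whitney(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.exponential(1.0, 60) ** 2, rng.exponential(1.5, 60) ** 2])
        groups = np.array([1] * 60 + [-1] * 60)
        assert compare_groups(values, groups, "continuous").test_used == "mann_whitney"


class TestLogisticFit:
    def test_binary_predictor_reproduces_cross_product_ratio(self):
        # 2x2 table a=20, b=10, c=10, d=20 -> OR = ad/bc = 4
        x = np.array([1.0] * 30 + [0.0] * 30)[:, None]
        y = np.array([1] * 20 + [-1] * 10 + [1] * 10 + [-1] * 20)
        fit = logistic_fit(x, y)
        assert fit.odds_ratios[0] == pytest.approx(4.0, abs=1e-8)
        assert fit.ci_lower[0] <= 4.0 <= fit.ci_upper[0]

    def test_all_zero_design_reduces_to_intercept_only(self):
        x = np.zeros((40, 2))
        y = np.array([1] * 10 + [-1] * 30)
        fit = logistic_fit(x, y)
        assert fit.names == []
        assert fit.intercept == pytest.approx(math.log(10 / 30), abs=1e-6)
        assert fit.odds_ratios.size == 0

    def test_perfect_separation_raises(self):
        x = np.array([-2.0, -1.0, -1.5, 1.0, 1.5, 2.0])[:, None]
        y = np.array([-1, -1, -1, 1, 1, 1])
        with pytest.raises(SeparationError):
            logistic_fit(x, y, names=["marker"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_statsmodels_oracle(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((150, 3))
        lp = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = np.where(rng.random(150) < 1.0 / (1.0 + np.exp(-lp)), 1, -1)
        fit = logistic_fit(X, y)
        ref = sm.GLM(
            (y == 1).astype(float), sm.add_constant(X), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(np.r_[fit.intercept, fit.coef], ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)


def _two_col_cohort(x1, x2, labels):
    schema = (ColumnSpec("u", "continuous"), ColumnSpec("v", "continuous"))
    return Cohort(pd.DataFrame({"u": x1, "v": x2}), labels, schema)


class TestCollinearity:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        labels = np.where(rng.random(100) < 0.4, 1, -1)
        cohort = _two_col_cohort(x, x.copy(), labels)
        retained, dropped, corr = collinearity_filter(cohort, ["u", "v"], 0.7)
        assert len(dropped) == 1 and len(retained) == 1
        assert corr.loc["u", "v"] == pytest.approx(1.0)

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(1)
        cohort = _two_col_cohort(
            rng.standard_normal(10_000),
            rng.standard_normal(10_000),
            np.where(rng.random(10_000) < 0.4, 1, -1),
        )
        retained, dropped, _ = collinearity_filter(cohort, ["u", "v"], 0.7)
        assert dropped == [] and retained == ["u", "v"]

    def test_less_significant_member_of_correlated_pair_dropped(self):
        """NEU carries the outcome signal, PLT rides along at r=0.8: PLT goes."""
        cohort = generate_cohort(GeneratorConfig(n=4000, seed=2))
        retained, dropped, _ = collinearity_filter(cohort, ["NEU", "PLT"], 0.7)
        assert dropped == ["PLT"]
        assert retained == ["NEU"]

    def test_empty_candidates_empty_output(self, small_cohort):
        retained, dropped, corr = collinearity_filter(small_cohort, [], 0.7)
        assert retained == [] and dropped == [] and corr.empty


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(GeneratorConfig(n=20_000, seed=5))


class TestScreens:

    def test_true_predictor_selected_univariately(self, big_cohort):
        _, selected = univariate_screen(big_cohort, alpha=0.05, candidates=["NEU"])
        assert selected == ["NEU"]

    def test_alpha_one_selects_everything(self, small_cohort):
        _, selected = univariate_screen(small_cohort, alpha=1.0)
        assert selected == [c.name for c in small_cohort.schema]

    def test_noise_column_false_positive_rate_near_alpha(self):
        """A pure-noise predictor should be selected at roughly rate alpha."""
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.standard_normal(120)[:, None]
            y = np.concatenate([np.ones(50), -np.ones(70)])
            fit = logistic_fit(x, y, names=["noise"])
            hits += fit.term_p("noise") <= 0.05
        assert 0.01 <= hits / reps <= 0.10  # ~3 sigma band around 0.05

    def test_backward_elimination_drops_noise_keeps_signal(self):
        cfg = GeneratorConfig(n=20_000, seed=9)
        cohort = generate_cohort(cfg)
        # GLU has a zero generator coefficient; NEU has a real one
        fit, trace = multivariate_select(cohort, ["NEU", "GLU"], alpha=0.05)
        assert "GLU" in trace
        assert "NEU" in fit.names

    def test_single_significant_variable_is_fixed_point(self, big_cohort):
        fit, trace = multivariate_select(big_cohort, ["NEU"], alpha=0.05)
        assert trace == []
        assert fit.names == ["NEU"]

    def test_alpha_zero_eliminates_everything(self, small_cohort):
        fit, trace = multivariate_select(small_cohort, ["NEU", "ALB"], alpha=0.0)
        assert fit.names == []
        assert set(trace) == {"NEU", "ALB"}

    def test_categorical_blocks_move_as_units(self, big_cohort):
        fit, _ = multivariate_select(big_cohort, ["intervention"], alpha=0.05)
        levels = [t for t in fit.names if t.startswith("intervention=")]
        # the whole block is either present or absent
        assert levels == [] or len(levels) == 3
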