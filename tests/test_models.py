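import itertools

import numpy as np
import pandas as pd
import pytest

from gaitkit import (
    BiomechEstimationModel,
    adjusted_r2,
    direction_order,
    hierarchical_regression,
    pearson_screen,
    run_model_suite,
    simulate_cohort,
    stepwise_select,
)
from gaitkit.exceptions import ModelError, ParameterError
from gaitkit.models import CATEGORIES, INERTIAL_VARS, group_by_category


def _brute_r(x, y):
    """Pearson r straight from the covariance formula."""
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def _brute_r2(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)


class TestAdjustedR2:
    def test_closed_form_example(self):
        assert adjusted_r2(0.5, 18, 3) == pytest.approx(1 - 0.5 * 17 / 14, abs=1e-12)

    def test_perfect_fit_stays_one(self):
        for n, p in [(18, 3), (10, 1), (100, 11)]:
            assert adjusted_r2(1.0, n, p) == 1.0

    def test_no_predictors_equals_r2(self):
        assert adjusted_r2(0.37, 18, 0) == pytest.approx(0.37)

    def test_undefined_when_saturated(self):
        with pytest.raises(ModelError):
            adjusted_r2(0.5, 5, 4)


class TestPearsonScreen:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=18)})
        screen = pearson_screen(x, x.rename(columns={"a": "t"}).assign(t=x["a"]))
        assert screen.r.loc["a", "t"] == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=18)
        screen = pearson_screen(pd.DataFrame({"a": x}), pd.DataFrame({"t": -x}))
        assert screen.r.loc["a", "t"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(18, 2)), columns=["a", "b"])
        Y = pd.DataFrame(rng.normal(size=(18, 2)), columns=["t1", "t2"])
        screen = pearson_screen(X, Y)
        for fx, fy in itertools.product(X.columns, Y.columns):
            assert screen.r.loc[fx, fy] == pytest.approx(
                _brute_r(X[fx].to_numpy(), Y[fy].to_numpy()), abs=1e-12
            )

    def test_zero_variance_reported_missing(self):
        X = pd.DataFrame({"a": np.ones(18)})
        Y = pd.DataFrame({"t": np.arange(18.0)})
        screen = pearson_screen(X, Y)
        assert np.isnan(screen.r.loc["a", "t"])
        assert screen.formatted.loc["a", "t"] == "-"

    def test_nonsignificant_entries_suppressed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"strong": x, "noise": rng.normal(size=50)})
        Y = pd.DataFrame({"t": 2 * x + rng.normal(0, 0.1, 50)})
        fmt = pearson_screen(X, Y).formatted
        assert fmt.loc["strong", "t"].endswith("**")
        assert fmt.loc["noise", "t"] == "-"


class TestDirectionOrder:
    @pytest.mark.parametrize(
        "target,expected",
        [
            ("kfm", ["anterior", "vertical", "lateral", "inclusive"]),
            ("kam", ["lateral", "anterior", "vertical", "inclusive"]),
            ("agrf", ["anterior", "vertical", "lateral", "inclusive"]),
            ("vgrf", ["vertical", "lateral", "anterior", "inclusive"]),
        ],
    )
    def test_cyclic_orders(self, target, expected):
        assert direction_order(target) == expected

    def test_unknown_target_rejected(self):
        with pytest.raises(ParameterError):
            direction_order("hip_moment")

    def test_categories_partition_all_inertial_variables(self):
        members = sorted(v for vs in CATEGORIES.values() for v in vs)
        assert members == sorted(INERTIAL_VARS)


class TestStepwise:
    def _data(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"x{i}" for i in range(5)])
        return X, rng

    def test_strong_single_predictor_selected_first(self):
        X, rng = self._data()
        y = 3.0 * X["x2"] + rng.normal(0, 0.01, 100)
        sel = stepwise_select(X, y, k_folds=10, seed=0)
        assert sel.selected[0] == "x2"
        # oracle: exhaustive search over single-variable models
        best = max(X.columns, key=lambda c: _brute_r2(X[[c]].to_numpy(), y))
        assert best == "x2"

    def test_duplicate_column_selected_once(self):
        X, rng = self._data()
        X["x2_copy"] = X["x2"]
        y = 3.0 * X["x2"] + rng.normal(0, 0.01, 100)
        sel = stepwise_select(X, y, k_folds=10, seed=0)
        assert ("x2" in sel.selected) != ("x2_copy" in sel.selected) or (
            "x2_copy" not in sel.selected
        )
        assert not ("x2" in sel.selected and "x2_copy" in sel.selected)

    def test_null_target_rarely_selects_anything(self):
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            X = pd.DataFrame(rng.normal(size=(100, 5)), columns=[f"x{i}" for i in range(5)])
            y = rng.normal(size=100)
            sel = stepwise_select(X, y, k_folds=10, seed=s)
            hits += bool(sel.selected)
            assert len(sel.selected) <= 2
        assert hits / 50 < 0.20

    def test_constant_target_selects_nothing(self):
        X, _ = self._data()
        with pytest.warns(UserWarning, match="constant"):
            sel = stepwise_select(X, np.ones(100), k_folds=10, seed=0)
        assert sel.selected == []

    def test_deterministic_given_seed(self):
        X, rng = self._data(seed=5)
        y = X["x0"] - 2 * X["x3"] + rng.normal(0, 0.2, 100)
        a = stepwise_select(X, y, seed=42)
        b = stepwise_select(X, y, seed=42)
        assert a.selected == b.selected

    def test_selected_set_never_worse_than_prefixes(self):
        X, rng = self._data(seed=8)
        y = X["x0"] + 0.5 * X["x1"] + rng.normal(0, 0.3, 100)
        sel = stepwise_select(X, y, seed=1)
        adjs = [
            adjusted_r2(_brute_r2(X[sel.selected[: k + 1]].to_numpy(), y), 100, k + 1)
            for k in range(len(sel.selected))
        ]
        assert all(a <= b + 1e-12 for a, b in zip(adjs[:-1], adjs[1:]))

    def test_too_few_subjects_for_folds_rejected(self):
        X, _ = self._data(n=100)
        with pytest.raises(ParameterError):
            stepwise_select(X.head(5), np.zeros(5), k_folds=10)


class TestHierarchicalRegression:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, len(INERTIAL_VARS))), columns=INERTIAL_VARS
        )
        return X, rng

    def test_noiseless_linear_reaches_adj_r2_one_any_order(self):
        X, _ = self._setup()
        y = 2 * X["mag_a"] - X["mag_l"] + 0.5 * X["st"]
        by_cat = group_by_category(["mag_a", "mag_l", "st"])
        for target in ("kfm", "kam", "agrf", "vgrf"):
            rep = hierarchical_regression(X, y, by_cat, direction_order(target))
            assert rep.steps["adj_r2"].iloc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_final_step_equals_one_shot_ols(self):
        X, rng = self._setup(seed=2)
        y = X["mag_a"] + 0.3 * X["imp_v"] + rng.normal(0, 0.5, 40)
        selected = ["mag_a", "imp_v", "vm"]
        rep = hierarchical_regression(
            X, y, group_by_category(selected), direction_order("kfm")
        )
        full_adj = adjusted_r2(_brute_r2(X[selected].to_numpy(), y), 40, 3)
        assert rep.steps["adj_r2"].iloc[-1] == pytest.approx(full_adj, abs=1e-10)

    def test_raw_r2_increments_telescope_to_full_model(self):
        X, rng = self._setup(seed=3)
        y = X["mag_a"] - X["ang_l"] + rng.normal(0, 0.4, 40)
        selected = ["mag_a", "ang_l", "st", "imp_v"]
        rep = hierarchical_regression(
            X, y, group_by_category(selected), direction_order("vgrf")
        )
        r2 = rep.steps["r2"].to_numpy()
        increments = np.diff(np.concatenate([[0.0], r2]))
        assert np.all(increments >= -1e-12)  # nested OLS never loses raw R^2
        assert increments.sum() == pytest.approx(r2[-1], abs=1e-12)

    def test_empty_category_contributes_zero_delta(self):
        X, rng = self._setup(seed=4)
        y = X["mag_a"] + rng.normal(0, 0.3, 40)
        rep = hierarchical_regression(
            X, y, group_by_category(["mag_a"]), direction_order("kfm")
        )
        steps = rep.steps.set_index("category")
        for cat in ("vertical", "lateral", "inclusive"):
            assert steps.loc[cat, "delta_r2"] == 0.0
            assert steps.loc[cat, "adj_r2"] == steps.loc["anterior", "adj_r2"]

    def test_empty_leading_category_reports_zero_r(self):
        X, rng = self._setup(seed=5)
        y = X["mag_l"] + rng.normal(0, 0.3, 40)
        rep = hierarchical_regression(
            X, y, group_by_category(["mag_l"]), direction_order("vgrf")
        )
        first = rep.steps.iloc[0]
        assert first["category"] == "vertical"
        assert first["R"] == 0.0 and first["adj_r2"] == 0.0

    def test_final_adj_r2_order_independent(self):
        X, rng = self._setup(seed=6)
        y = X["mag_a"] + X["mag_l"] + rng.normal(0, 0.5, 40)
        by_cat = group_by_category(["mag_a", "mag_l", "vm"])
        finals = {
            t: hierarchical_regression(X, y, by_cat, direction_order(t)).steps["adj_r2"].iloc[-1]
            for t in ("kfm", "kam", "vgrf")
        }
        vals = list(finals.values())
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_singular_design_raises_naming_step(self):
        X, rng = self._setup(seed=7)
        X["imp_a"] = X["mag_a"]  # exact collinearity inside one category
        y = X["mag_a"] + rng.normal(0, 0.3, 40)
        with pytest.raises(ModelError, match="anterior"):
            hierarchical_regression(
                X, y, group_by_category(["mag_a", "imp_a"]), direction_order("kfm")
            )


@pytest.fixture(scope="module")
def cohort():
    spec = {"agrf": {"coef": {"mag_a": 0.9, "ang_a": 0.25}, "intercept": 0.6, "noise_sd": 0.05}}
    return simulate_cohort(
        n_subjects=18, effect_spec=spec, seed=5, include_traces=False, n_strides=8
    )


class TestModelResults:
    def test_fit_reports_selected_and_steps(self, cohort):
        res = BiomechEstimationModel.from_summary_table(cohort.summary, "agrf").fit(seed=0)
        assert "mag_a" in res.selected
        assert list(res.steps["category"]) == direction_order("agrf")
        assert res.rsquared_adj > 0.5

    def test_summary_text_contains_step_table(self, cohort):
        res = BiomechEstimationModel.from_summary_table(cohort.summary, "agrf").fit(seed=0)
        text = res.summary()
        assert "AGRF" in text and "anterior" in text and "coef" in text

    def test_refit_same_seed_identical(self, cohort):
        m = BiomechEstimationModel.from_summary_table(cohort.summary, "agrf")
        a, b = m.fit(seed=3), m.fit(seed=3)
        pd.testing.assert_frame_equal(a.steps, b.steps)
        assert a.selected == b.selected

    def test_missing_columns_rejected(self, cohort):
        with pytest.raises(ParameterError):
            BiomechEstimationModel.from_summary_table(
                cohort.summary.drop(columns=["avg_mag_a"]), "agrf"
            )


class TestModelSuite:
    def test_outlier_branch_uses_reduced_cohort(self):
        cohort = simulate_cohort(n_subjects=18, seed=1, include_traces=False, n_strides=8)
        summary = cohort.summary.copy()
        summary.loc[4, "avg_vgrf"] *= 10
        suite = run_model_suite(summary, mode="average", seed=0)
        assert suite.outlier_ids == [summary.loc[4, "subject_id"]]
        assert suite.excluding_outliers is not None
        assert suite.excluding_outliers["kfm"].nobs == 17
        assert suite.all_subjects["kfm"].nobs == 18

    def test_clean_cohort_skips_exclusion_branch(self):
        cohort = simulate_cohort(n_subjects=12, seed=2, include_traces=False, n_strides=8)
        suite = run_model_suite(cohort.summary, mode="average", seed=0, mad_cutoff=6.0)
        assert suite.excluding_outliers is None
        assert set(suite.all_subjects) == {"kfm", "kam", "agrf", "vgrf"}
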