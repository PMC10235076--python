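import math

import numpy as np
import pandas as pd
import pytest

from telogel.cohortstats import (
    COHORT_COLUMNS,
    aic_select,
    all_subsets_r2,
    bh_adjust,
    commonality,
    correlation_matrix,
    fit_tl_size_models,
    ols_fit,
    validate_cohort,
)
from telogel.synthetic import CohortDesign, simulate_cohort


def make_cohort(ln_tl, diameter, island=None, genus="Pocillopora"):
    n = len(ln_tl)
    table = pd.DataFrame({c: [""] * n for c in COHORT_COLUMNS})
    table["colony_id"] = [f"C{i}" for i in range(n)]
    table["island"] = island if island is not None else "I01"
    table["genus"] = genus
    table["symbiodiniaceae_profile"] = "P1"
    table["bacteria_profile"] = "B1"
    table["diameter_cm"] = diameter
    for col in [c for c in COHORT_COLUMNS if c.endswith("_kb")]:
        table[col] = np.exp(ln_tl)
    return table


class TestOlsFit:
    def test_perfect_fit(self):
        x = np.arange(20.0)
        fit = ols_fit(3.0 - 0.5 * x, {"x": x})
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.aic < -1e11  # sentinel, still orderable

    def test_constant_response_r2_zero(self):
        fit = ols_fit(np.full(15, 4.2), {"x": np.arange(15.0)})
        assert fit.r2 == 0.0

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(size=(2, 60))
        island = rng.choice(["A", "B", "C"], size=60)
        y = 1 + 2 * x1 - x2 + (island == "B") * 0.5 + rng.normal(size=60)
        fit = ols_fit(y, {"x1": x1, "x2": x2, "island": pd.Series(island)})
        dummies = pd.get_dummies(pd.Series(island), prefix="island", drop_first=True)
        X = np.column_stack([np.ones(60), x1, x2, dummies.to_numpy(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        rss = resid @ resid
        r2 = 1 - rss / ((y - y.mean()) ** 2).sum()
        assert fit.r2 == pytest.approx(r2, rel=1e-10)
        assert fit.rss == pytest.approx(rss, rel=1e-10)
        # R-style Gaussian AIC with the error variance as a parameter
        n, k = 60, X.shape[1] + 1
        aic = n * math.log(2 * math.pi) + n * math.log(rss / n) + n + 2 * k
        assert fit.aic == pytest.approx(aic, rel=1e-12)

    def test_aliased_column_dropped_with_warning(self):
        x = np.arange(30.0)
        with pytest.warns(UserWarning, match="aliased"):
            fit = ols_fit(x + 1.0, {"x": x, "x_copy": x.copy()})
        assert len(fit.dropped_aliased) == 1

    def test_adjusted_r2_bounded(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        fit = ols_fit(y, {"x": rng.normal(size=40)})
        assert fit.adj_r2 <= fit.r2 <= 1.0


class TestSizeModelFamily:
    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(5, 100, 300)
        ln_tl = 2.0 - 0.01 * d + rng.normal(0, 0.1, 300)
        fits = fit_tl_size_models(make_cohort(ln_tl, d))
        best = aic_select(fits)
        assert best.formula.endswith("~ diameter")
        assert best.slope < 0
        se = abs(best.slope + 0.01) / max(abs(best.slope), 1e-9)
        assert best.slope == pytest.approx(-0.01, abs=3 * 0.1 / math.sqrt(300))

    def test_quadratic_truth_selects_quadratic(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(5, 100, 200)
        ln_tl = 1.0 + 0.03 * d - 0.0004 * d**2 + rng.normal(0, 0.05, 200)
        best = aic_select(fit_tl_size_models(make_cohort(ln_tl, d)))
        assert "diameter^2" in best.formula

    def test_null_effect_rarely_significant(self):
        rng = np.random.default_rng(3)
        n_sig = {"linear": 0, "quadratic": 0, "log": 0}
        n_reps = 100
        for _ in range(n_reps):
            d = rng.uniform(5, 100, 80)
            ln_tl = 1.5 + rng.normal(0, 0.3, 80)
            fits = fit_tl_size_models(make_cohort(ln_tl, d))
            for key, f in zip(n_sig, fits):
                n_sig[key] += f.slope_p < 0.05
        for key, count in n_sig.items():
            assert count / n_reps <= 0.10, f"{key}: {count}/{n_reps} significant"

    def test_too_few_colonies(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_tl_size_models(make_cohort(np.ones(5), np.arange(1.0, 6.0)))


class TestAicSelect:
    def _fit(self, y, x):
        return ols_fit(y, {"x": x})

    def test_lowest_aic_wins(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        good = ols_fit(y, {"x": x})
        bad = ols_fit(y, {"noise": rng.normal(size=50)})
        assert aic_select([bad, good]) is good

    def test_tie_prefers_fewer_parameters(self):
        from telogel.cohortstats import ModelFit

        a = ModelFit("small", {}, 0.5, 0.4, 10.0, 30, 27, 2, 1.0, response_tag=1)
        b = ModelFit("big", {}, 0.5, 0.4, 10.0, 30, 26, 3, 1.0, response_tag=1)
        assert aic_select([b, a]) is a

    def test_single_fit(self):
        rng = np.random.default_rng(6)
        f = self._fit(rng.normal(size=20), rng.normal(size=20))
        assert aic_select([f]) is f

    def test_different_subsets_refused(self):
        rng = np.random.default_rng(7)
        f1 = self._fit(rng.normal(size=20), rng.normal(size=20))
        f2 = self._fit(rng.normal(size=25), rng.normal(size=25))
        with pytest.raises(ValueError, match="not comparable"):
            aic_select([f1, f2])


class TestCommonality:
    def test_single_predictor(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        r2map = all_subsets_r2(y, {"x": x})
        res = commonality(r2map)
        assert res.unique("x") == pytest.approx(r2map[frozenset(["x"])])
        assert res.percentages[frozenset(["x"])] == pytest.approx(100.0)

    def test_orthogonal_predictors_additive(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(11)
        y = x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
        y = y - y.mean()
        r2map = all_subsets_r2(y, {"x1": x1, "x2": x2})
        both = r2map[frozenset(["x1", "x2"])]
        assert both == pytest.approx(
            r2map[frozenset(["x1"])] + r2map[frozenset(["x2"])], abs=1e-8
        )
        res = commonality(r2map)
        assert res.coefficients[frozenset(["x1", "x2"])] == pytest.approx(0.0, abs=1e-8)
        assert res.unique("x1") == pytest.approx(r2map[frozenset(["x1"])], abs=1e-8)

    def test_duplicated_predictor_fully_common(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        y = x + rng.normal(0, 1.2, 200)
        # X2 an exact copy of X1: all explained variance is common
        r2_x = ols_fit(y, {"x": x}).r2
        r2map = {
            frozenset(["x1"]): r2_x,
            frozenset(["x2"]): r2_x,
            frozenset(["x1", "x2"]): r2_x,
        }
        res = commonality(r2map)
        assert res.unique("x1") == pytest.approx(0.0, abs=1e-12)
        assert res.unique("x2") == pytest.approx(0.0, abs=1e-12)
        assert res.coefficients[frozenset(["x1", "x2"])] == pytest.approx(r2_x)

    def test_coefficients_sum_to_full_r2_and_unique_identity(self):
        rng = np.random.default_rng(13)
        n = 150
        blocks = {
            "island": pd.Series(rng.choice(list("ABCDE"), n)),
            "community": pd.Series(rng.choice(["c1", "c2", "c3"], n)),
            "diam": rng.uniform(5, 100, n),
        }
        y = (
            (blocks["island"] == "A") * 0.8
            + (blocks["community"] == "c1") * 0.3
            + 0.002 * blocks["diam"]
            + rng.normal(0, 0.5, n)
        ).to_numpy()
        r2map = all_subsets_r2(y, blocks)
        res = commonality(r2map)
        full = frozenset(blocks)
        assert sum(res.coefficients.values()) == pytest.approx(r2map[full], abs=1e-10)
        for name in blocks:
            drop = r2map[full] - r2map[full - {name}]
            assert res.unique(name) == pytest.approx(drop, abs=1e-10)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_incomplete_map_refused(self):
        with pytest.raises(ValueError, match="incomplete"):
            commonality({frozenset(["a"]): 0.3, frozenset(["a", "b"]): 0.5})

    def test_table_layout(self):
        res = commonality({
            frozenset(["island"]): 0.4,
            frozenset(["bacteria"]): 0.2,
            frozenset(["island", "bacteria"]): 0.5,
        })
        frame = res.to_frame()
        assert list(frame.columns) == ["subset", "coefficient", "percent_of_total"]
        assert frame["subset"].iloc[-1] == "Total"
        assert frame["coefficient"].iloc[-1] == pytest.approx(0.5)
        assert "Unique to island" in set(frame["subset"])
        assert "Common to bacteria, and island" in set(frame["subset"])


class TestDesignedVarianceRecovery:
    def test_island_fraction_recovered(self):
        # island 50% / community 10% / residual 40% of ln(TL) variance
        recovered, designed = [], []
        for rep in range(12):
            table, truth = simulate_cohort(CohortDesign(seed=100 + rep))
            y = np.log(table["htl_mean_kb"].to_numpy())
            blocks = {
                "island": table["island"],
                "community": table["symbiodiniaceae_profile"],
            }
            res = commonality(all_subsets_r2(y, blocks))
            recovered.append(100 * res.unique("island"))
            designed.append(100 * truth["fractions"]["island"])
        assert abs(np.mean(recovered) - 50.0) <= 8.0
        # per-replicate recovery tracks the realized island variance
        assert np.median(np.abs(np.array(recovered) - np.array(designed))) <= 8.0


class TestCorrelations:
    def test_monotone_transform_spearman_one(self):
        x = np.linspace(-2, 2, 30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        cm = correlation_matrix(df, method="spearman")
        assert cm.coef.loc["x", "y"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.linspace(0, 5, 25)
        cm = correlation_matrix(pd.DataFrame({"x": x, "y": -x}), method="pearson")
        assert cm.coef.loc["x", "y"] == pytest.approx(-1.0)

    def test_bh_stepup_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_monotone_under_permutation(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        cm = correlation_matrix(df, method="spearman")
        raw = cm.pvalue.to_numpy().ravel()
        adj = cm.pvalue_adjusted.to_numpy().ravel()
        ok = np.isfinite(raw)
        assert np.all(adj[ok] >= raw[ok] - 1e-12)
        assert np.allclose(cm.coef.to_numpy(), cm.coef.to_numpy().T)
        assert np.allclose(np.diag(cm.coef), 1.0)

    def test_constant_column_missing_not_zero(self):
        df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        cm = correlation_matrix(df)
        assert np.isnan(cm.coef.loc["x", "c"])


class TestCohortSchema:
    def test_missing_column(self):
        table, _ = simulate_cohort(CohortDesign(n_islands=3, colonies_per_island=4))
        with pytest.raises(ValueError, match="missing columns"):
            validate_cohort(table.drop(columns=["island"]))

    def test_duplicate_colony_id(self):
        table, _ = simulate_cohort(CohortDesign(n_islands=3, colonies_per_island=4))
        table.loc[1, "colony_id"] = table.loc[0, "colony_id"]
        with pytest.raises(ValueError, match="duplicated"):
            validate_cohort(table)

    def test_valid_table_passes(self):
        table, _ = simulate_cohort(CohortDesign(n_islands=3, colonies_per_island=4))
        assert validate_cohort(table) is table
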