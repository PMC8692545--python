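"""Statistical-procedure tests: standardisation, VIF, OLS/AICc, averaging.

The OLS path is cross-checked against two independent routes: a brute-force
normal-equations solve written here, and statsmodels.
"""

import math

import numpy as np
import pytest

from isoarctic.attribution import (
    CellSeries,
    DegeneratePredictorError,
    EXCLUDED,
    ESTIMATED,
    NONSIG,
    REANALYSIS_PREDICTORS,
    attribute_cell,
    attribute_cells,
    attribution_table,
    candidate_models,
    fit_ols,
    select_and_average,
    standardize,
    vif,
)
from isoarctic.synthetic import SyntheticSpec, generate


def brute_force_ols(y, X):
    """Independent oracle: normal equations via explicit inverse."""
    n, p = X.shape
    D = np.column_stack([np.ones(n), X])
    xtx_inv = np.linalg.inv(D.T @ D)
    beta = xtx_inv @ D.T @ y
    resid = y - D @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p - 1)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    k = p + 2
    aicc = n * math.log(max(rss, 1e-12 * float(y @ y)) / n) + 2 * k \
        + 2 * k * (k + 1) / (n - k - 1)
    return beta, se, rss, aicc


class TestStandardize:
    def test_hand_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        x = standardize(np.random.default_rng(0).normal(size=40))
        np.testing.assert_allclose(standardize(x), x, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        np.testing.assert_allclose(standardize(3.7 * x - 11.0), standardize(x),
                                   atol=1e-10)

    def test_moments(self):
        z = standardize(np.arange(25, dtype=float) ** 2)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_is_error(self):
        with pytest.raises(DegeneratePredictorError):
            standardize(np.full(20, 3.3))


class TestVIF:
    def test_orthogonal_columns_are_one(self):
        n = 40
        t = np.arange(n)
        x1 = standardize(np.sin(2 * np.pi * t / 8))
        x2 = standardize(np.cos(2 * np.pi * t / 8))
        v = vif(np.column_stack([x1, x2]))
        assert np.allclose(v, 1.0, atol=0.05)

    def test_near_duplicate_exceeds_threshold(self):
        rng = np.random.default_rng(2)
        x1 = standardize(rng.normal(size=50))
        x2 = standardize(x1 + rng.normal(scale=0.01, size=50))
        assert vif(np.column_stack([x1, x2])).min() > 3.0

    def test_exact_correlation_closed_form(self):
        # construct two columns with sample correlation exactly 0.8
        n = 50
        rng = np.random.default_rng(3)
        a = standardize(rng.normal(size=n))
        b = rng.normal(size=n)
        b = standardize(b - a * (a @ b) / (a @ a))  # orthogonal to a
        x2 = standardize(0.8 * a + math.sqrt(1 - 0.64) * b)
        v = vif(np.column_stack([a, x2]))
        assert np.allclose(v, 1.0 / (1.0 - 0.64), atol=1e-9)

    def test_perfect_collinearity_reported_infinite(self):
        x = standardize(np.arange(30, dtype=float))
        v = vif(np.column_stack([x, x]))
        assert np.isinf(v).all()

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(4)
        X = np.column_stack([standardize(rng.normal(size=60)) for _ in range(3)])
        X[:, 2] = standardize(X[:, 0] + 0.5 * rng.normal(size=60))
        ours = vif(X)
        theirs = [variance_inflation_factor(X, j) for j in range(3)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)


class TestFitOLS:
    def test_exact_fit_coefficient(self):
        x = standardize(np.arange(20, dtype=float))
        res = fit_ols(2.0 * x, {"x": x}, ("x",))
        assert res.coef["x"] == pytest.approx(2.0, abs=1e-10)
        assert math.isfinite(res.aicc)

    def test_null_model_closed_form(self):
        y = np.array([1.0, 2.0, 4.0, 9.0, 4.0])
        res = fit_ols(y, {}, ())
        assert res.intercept == pytest.approx(y.mean())
        assert res.rss == pytest.approx(((y - y.mean()) ** 2).sum())
        assert res.k == 2

    def test_matches_brute_force_on_random_designs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(12, 31)
            p = rng.integers(1, 4)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            names = tuple(f"x{j}" for j in range(p))
            res = fit_ols(y, {nm: X[:, j] for j, nm in enumerate(names)}, names)
            beta, se, rss, aicc = brute_force_ols(y, X)
            assert res.intercept == pytest.approx(beta[0], rel=1e-8, abs=1e-10)
            for j, nm in enumerate(names):
                assert res.coef[nm] == pytest.approx(beta[j + 1], rel=1e-8, abs=1e-10)
                assert res.se[nm] == pytest.approx(se[j + 1], rel=1e-8, abs=1e-10)
            assert res.rss == pytest.approx(rss, rel=1e-8, abs=1e-12)
            assert res.aicc == pytest.approx(aicc, rel=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 3))
        y = X @ np.array([0.5, -1.0, 0.2]) + rng.normal(size=25)
        names = ("a", "b", "c")
        res = fit_ols(y, dict(zip(names, X.T)), names)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            [res.intercept] + [res.coef[nm] for nm in names], ref.params, rtol=1e-9
        )
        np.testing.assert_allclose(
            [res.se[nm] for nm in names], ref.bse[1:], rtol=1e-9
        )

    def test_singular_design_raises(self):
        x = standardize(np.arange(20, dtype=float))
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(x, {"a": x, "b": x}, ("a", "b"))


class TestSelectAndAverage:
    def _fits(self, y, X, mode="reanalysis"):
        fits, null = [], None
        for subset in candidate_models(mode):
            f = fit_ols(y, X, subset)
            if subset:
                fits.append(f)
            else:
                null = f
        return fits, null

    def test_single_model_confidence_set_degenerates(self):
        # one overwhelming predictor: the best model dominates and the
        # averaged estimate equals its conditional estimate
        rng = np.random.default_rng(7)
        x = standardize(rng.normal(size=60))
        X = {"salinity": x,
             "nstar": standardize(rng.normal(size=60)),
             "pom": standardize(rng.normal(size=60))}
        y = 5.0 * x + rng.normal(scale=0.05, size=60)
        fits, null = self._fits(y, X)
        status, effects = select_and_average(fits, null, REANALYSIS_PREDICTORS)
        assert status == ESTIMATED
        best_fit = min((f for f in fits if f.aicc < null.aicc), key=lambda f: f.aicc)
        e = effects["salinity"]
        assert e.estimate == pytest.approx(best_fit.coef["salinity"], rel=1e-3)
        assert e.significant and e.ci_low > 0

    def test_null_best_gives_all_nonsignificant(self):
        rng = np.random.default_rng(8)
        # tiny n with pure noise: null usually wins; find a seed where it does
        X = {nm: standardize(rng.normal(size=15)) for nm in REANALYSIS_PREDICTORS}
        y = np.asarray(standardize(rng.normal(size=15)))
        fits, null = self._fits(y, X)
        fits_above = [f for f in fits if f.aicc >= null.aicc]
        if len(fits_above) == len(fits):
            status, effects = select_and_average(fits, null, REANALYSIS_PREDICTORS)
            assert status == NONSIG and effects == {}

    def test_weights_invariant_to_candidate_order(self):
        rng = np.random.default_rng(9)
        X = {nm: standardize(rng.normal(size=40)) for nm in REANALYSIS_PREDICTORS}
        y = 0.8 * X["pom"] + rng.normal(scale=0.5, size=40)
        fits, null = self._fits(y, X)
        s1, e1 = select_and_average(fits, null, REANALYSIS_PREDICTORS)
        s2, e2 = select_and_average(list(reversed(fits)), null, REANALYSIS_PREDICTORS)
        assert s1 == s2
        for nm in REANALYSIS_PREDICTORS:
            assert e1[nm].estimate == pytest.approx(e2[nm].estimate, rel=1e-12)
            assert e1[nm].ci_low == pytest.approx(e2[nm].ci_low, rel=1e-12)


class TestCandidateSets:
    def test_reanalysis_has_eight_models(self):
        models = candidate_models("reanalysis")
        assert len(models) == 8 and () in models

    def test_emissions_has_four_models(self):
        models = candidate_models("emissions")
        assert len(models) == 4 and () in models
        assert all(set(m) <= {"nstar", "pom"} for m in models)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            candidate_models("historical")


class TestPipeline:
    def test_noiseless_recovery(self):
        cells, _ = generate(SyntheticSpec(n_cells=5, beta=(0.0, -1.0, 1.0),
                                          noise_sd=0.0, seed=11))
        for cell in cells:
            res = attribute_cell(cell, "reanalysis")
            assert res.status == ESTIMATED
            assert res.effects["nstar"].estimate == pytest.approx(-1.0, abs=1e-6)
            assert res.effects["pom"].estimate == pytest.approx(1.0, abs=1e-6)
            assert abs(res.effects["salinity"].estimate) < 1e-6

    def test_parameter_recovery_low_noise(self):
        cells, _ = generate(SyntheticSpec(n_cells=20, beta=(0.0, 2.0, 0.0),
                                          noise_sd=0.1, seed=12))
        results = attribute_cells(cells, "reanalysis")
        for r in results:
            assert r.status == ESTIMATED
            e = r.effects["nstar"]
            assert e.significant and e.estimate == pytest.approx(2.0, abs=0.15)
            assert r.best_predictor == "nstar"

    def test_collinear_cells_excluded(self):
        cells, truth = generate(SyntheticSpec(n_cells=10, collinear_fraction=1.0,
                                              beta=(0.5, 0.5, 0.5),
                                              noise_sd=0.3, seed=13))
        results = attribute_cells(cells, "reanalysis")
        assert all(r.status == EXCLUDED for r in results)
        assert truth["collinear"].all()

    def test_malformed_cells_flagged_not_raised(self):
        years = np.arange(1970, 2020)
        good = np.random.default_rng(14).normal(size=50)
        bad_nan = CellSeries("bad_nan", years, good, good * 0 + np.nan, good, good)
        bad_short = CellSeries("bad_short", years[:5], good[:5], good[:5],
                               good[:5], good[:5])
        bad_const = CellSeries("bad_const", years, np.ones(50), good, good, good)
        table = attribution_table(attribute_cells([bad_nan, bad_short, bad_const]),
                                  "reanalysis")
        assert (table["status"] == "skipped").all()
        assert table["skip_reason"].str.len().gt(0).all()

    def test_emissions_mode_ignores_salinity(self):
        rng = np.random.default_rng(15)
        n = 50
        sal = standardize(rng.normal(size=n))
        cell = CellSeries("c", np.arange(n), sal,
                          standardize(rng.normal(size=n)),
                          standardize(rng.normal(size=n)),
                          5.0 * sal + rng.normal(scale=0.1, size=n))
        res = attribute_cell(cell, "emissions")
        assert "salinity" not in res.effects
        assert res.status in (ESTIMATED, NONSIG)

    def test_thresholds_are_adjustable(self):
        cells, _ = generate(SyntheticSpec(n_cells=5, collinear_fraction=1.0,
                                          beta=(0.5, 0.5, 0.5), noise_sd=0.3,
                                          seed=16))
        relaxed = attribute_cells(cells, "reanalysis", vif_threshold=1e9)
        assert all(r.status != EXCLUDED for r in relaxed)
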