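"""Weighted logistic RSF: oracles, invariances, pooling, RSS, validation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from owlrsf import rsf
from owlrsf.errors import RankError, SchemaError


def weighted_loglik(beta, X, y, w):
    eta = X @ beta
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def random_tiny_design(rng, n_rows=None, n_cov=None):
    n = n_rows or int(rng.integers(8, 21))
    p = n_cov or int(rng.integers(1, 3))
    X = np.column_stack([np.ones(n)] + [rng.normal(0, 1, n) for _ in range(p)])
    y = (rng.random(n) < 0.4).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    if y.sum() == len(y):
        y[0] = 0.0
    w = np.where(y == 1, 1.0, float(rng.choice([1.0, 10.0, 5000.0])))
    return pd.DataFrame(X, columns=["intercept"] + [f"x{i}" for i in range(p)]), y, w


class TestFitOracles:
    def test_intercept_only_closed_form(self):
        n_u, n_a, W = 37, 911, 5000.0
        y = np.concatenate([np.ones(n_u), np.zeros(n_a)])
        X = pd.DataFrame({"intercept": np.ones(n_u + n_a)})
        w = np.where(y == 1, 1.0, W)
        fit = rsf.fit_weighted_logistic(X=X, y=y, weights=w)
        assert fit.beta["intercept"] == pytest.approx(np.log(n_u / (W * n_a)), abs=1e-10)

    def test_matches_brute_force_optimiser_on_tiny_designs(self):
        rng = np.random.default_rng(100)
        for _ in range(10):
            X, y, w = random_tiny_design(rng)
            fit = rsf.fit_weighted_logistic(X=X, y=y, weights=w)
            res = minimize(
                lambda b: -weighted_loglik(b, X.to_numpy(), y, w),
                np.zeros(X.shape[1]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000},
            )
            assert np.allclose(fit.beta.to_numpy(), res.x, atol=1e-4)

    def test_ipp_slope_recovery(self, recovery_table):
        from .conftest import recovery_design

        truth, table = recovery_table
        fit = rsf.fit_weighted_logistic(design=recovery_design(table))
        assert fit.converged
        for term, true_beta in (("intensive_grassland", 1.0), ("forest", -1.0)):
            assert abs(fit.beta[term] - true_beta) < 3 * fit.se[term]


class TestInvariances:
    def test_weight_rescaling_moves_only_the_intercept(self, recovery_table):
        from .conftest import recovery_design

        _, table = recovery_table
        d = recovery_design(table)
        f1 = rsf.fit_weighted_logistic(design=d)
        f2 = rsf.fit_weighted_logistic(
            X=d.X, y=d.y, weights=np.where(d.y == 0, d.weights * 7.0, d.weights)
        )
        slopes = [c for c in d.X.columns if c != "intercept"]
        assert np.allclose(f1.beta[slopes], f2.beta[slopes], atol=1e-6)
        assert abs(f1.beta["intercept"] - f2.beta["intercept"]) > 0.1

    def test_rss_ratios_invariant_to_reference_relabelling(self, recovery_table):
        _, table = recovery_table
        d_crop = rsf.build_design(table, "habitat")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_crop = rsf.fit_weighted_logistic(design=d_crop)
            # refit with forest as the reference category
            X = d_crop.X.copy()
            X["dominant_crop_rotation"] = (
                1.0
                - X[[c for c in X.columns if c.startswith("dominant_")]].sum(axis=1)
            )
            X = X.drop(columns=["dominant_forest"])
            f_forest = rsf.fit_weighted_logistic(
                X=X, y=d_crop.y, weights=d_crop.weights
            )
        # RSS ratio grassland/urban must not depend on the reference
        ratio_crop = np.exp(
            f_crop.beta["dominant_intensive_grassland"] - f_crop.beta["dominant_urban"]
        )
        ratio_forest = np.exp(
            f_forest.beta["dominant_intensive_grassland"]
            - f_forest.beta["dominant_urban"]
        )
        assert ratio_crop == pytest.approx(ratio_forest, rel=1e-6)

    def test_separation_flagged(self):
        X = pd.DataFrame({"intercept": np.ones(20), "x": np.r_[np.ones(10), -np.ones(10)]})
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = rsf.fit_weighted_logistic(X=X, y=y)
        assert not fit.converged
        assert "separation" in fit.message

    def test_rank_deficiency_names_aliased_columns(self):
        rng = np.random.default_rng(102)
        x = rng.normal(size=50)
        X = pd.DataFrame({"intercept": 1.0, "a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(RankError) as exc:
            rsf.fit_weighted_logistic(X=X, y=y)
        assert set(exc.value.aliased) & {"a", "b"}


class TestDesign:
    def test_reference_coding_and_scaling(self, recovery_table):
        _, table = recovery_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = rsf.build_design(table, "habitat")
        d.check_invariants()
        crop_rows = d.X.loc[
            table.loc[d.X.index, "dominant"] == "crop_rotation",
            [c for c in d.X.columns if c.startswith("dominant_")],
        ]
        assert (crop_rows.to_numpy() == 0).all()

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(SchemaError):
            rsf.build_design(pd.DataFrame({"case": []}), "habitat")
        with pytest.raises(SchemaError):
            rsf.build_design(pd.DataFrame({"case": []}), "nonsense")

    def test_total_prey_design_keeps_five_habitat_columns(self, recovery_table):
        _, table = recovery_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = rsf.build_design(table, "total_prey")
        prey_cols = [c for c in d.X.columns if c.startswith("total_prey_")]
        # grasslands stay split by default; merge is a separate option
        assert "total_prey_intensive_grassland" in prey_cols
        assert "total_prey_extensive_grassland" in prey_cols


class TestPopulationPooling:
    def _fake_fit(self, beta, var, model="habitat"):
        terms = list(beta.keys())
        return rsf.RSFFit(
            beta=pd.Series(beta),
            cov=pd.DataFrame(np.diag(list(var.values())), index=terms, columns=terms),
            n_used=100,
            n_available=10_000,
            converged=True,
            n_iter=5,
            model=model,
        )

    def test_identical_deployments_pool_to_same_estimate(self):
        fits = [self._fake_fit({"x": 0.7}, {"x": 0.01}) for _ in range(5)]
        pooled = rsf.fit_population(fits)
        assert pooled.beta["x"] == pytest.approx(0.7)
        assert pooled.between_variance["x"] == 0.0

    def test_between_deployment_variance_recovered(self):
        rng = np.random.default_rng(200)
        tau2_true = 0.25
        fits = [
            self._fake_fit(
                {"x": float(rng.normal(0.5, np.sqrt(tau2_true)) + rng.normal(0, 0.1))},
                {"x": 0.01},
            )
            for _ in range(30)
        ]
        pooled = rsf.fit_population(fits)
        assert tau2_true / 2 <= pooled.between_variance["x"] <= tau2_true * 2

    def test_pooled_se_shrinks_with_deployments(self):
        fits = [self._fake_fit({"x": 0.5}, {"x": 0.04}) for _ in range(10)]
        pooled = rsf.fit_population(fits)
        assert pooled.se["x"] < np.sqrt(0.04)
        assert pooled.n_deployments == 10

    def test_no_converged_fits_raises(self):
        bad = self._fake_fit({"x": 0.1}, {"x": 1.0})
        bad.converged = False
        with pytest.raises(RankError):
            rsf.fit_population([bad])


class TestRSS:
    def test_printed_coefficient_arithmetic(self):
        # exp of log relative-selection coefficients at 2 dp
        terms = {"grassland": 0.25, "forest": -0.60, "reference": 0.0}
        fit = rsf.RSFFit(
            beta=pd.Series(terms),
            cov=pd.DataFrame(
                np.eye(3) * 1e-6, index=list(terms), columns=list(terms)
            ),
            n_used=1,
            n_available=1,
            converged=True,
            n_iter=1,
        )
        rep = rsf.rss(fit, seed=0).table.set_index("term")
        assert round(rep.loc["grassland", "rss"], 2) == 1.28
        assert round(rep.loc["forest", "rss"], 2) == 0.55
        assert rep.loc["reference", "rss"] == pytest.approx(1.0)

    def test_interval_is_exp_of_draw_quantiles(self):
        fit = rsf.RSFFit(
            beta=pd.Series({"x": 0.3}),
            cov=pd.DataFrame([[0.01]], index=["x"], columns=["x"]),
            n_used=1,
            n_available=1,
            converged=True,
            n_iter=1,
        )
        rep = rsf.rss(fit, n_draws=5000, seed=1).table.iloc[0]
        assert rep["rss_lo"] == pytest.approx(np.exp(0.3 - 1.96 * 0.1), rel=0.03)
        assert rep["rss_hi"] == pytest.approx(np.exp(0.3 + 1.96 * 0.1), rel=0.03)
        assert rep["meaningful"]
        assert rep["rss_draw_mean"] > rep["rss"]  # Jensen


class TestSensitivityAndValidation:
    def test_ratio_rows_honoured_and_slopes_stable(self, recovery_table):
        _, table = recovery_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens = rsf.ratio_sensitivity(table, "habitat", ratios=(10, 100), seed=0)
        assert set(sens["ratio"]) == {10, 100}
        piv = sens.pivot(index="term", columns="ratio", values="beta").drop("intercept")
        se = sens[sens["ratio"] == 100].set_index("term")["se"]
        assert ((piv[10] - piv[100]).abs() / se.loc[piv.index] < 2).all()

    def test_ratio_one_has_wider_se_than_hundred(self, recovery_table):
        _, table = recovery_table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens = rsf.ratio_sensitivity(table, "habitat", ratios=(1, 100), seed=0)
        se = sens.pivot(index="term", columns="ratio", values="se").drop("intercept")
        assert (se[1] > se[100]).all()

    def test_calibration_slope_near_one(self, recovery_table):
        from .conftest import recovery_design

        _, table = recovery_table
        val = rsf.cross_validate(recovery_design(table), seed=0)
        assert 0.8 <= val.slope <= 1.2

    def test_permuted_predictions_have_zero_slope(self, recovery_table):
        from .conftest import recovery_design

        _, table = recovery_table
        val = rsf.cross_validate(recovery_design(table), seed=0, permute=True)
        assert -0.2 <= val.slope <= 0.2

    def test_degenerate_binning_raises(self):
        X = pd.DataFrame({"intercept": np.ones(40), "x": np.zeros(40)})
        y = np.r_[np.ones(10), np.zeros(30)]
        design = rsf.RSFDesign(
            X=X, y=y, weights=np.ones(40), groups=np.zeros(40), model="t"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises((SchemaError, RankError)):
                rsf.cross_validate(design, n_bins=10, seed=0)
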