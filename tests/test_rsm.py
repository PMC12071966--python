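import numpy as np
import pytest

from _oracles import normal_equations_fit
from exoenrich import datasets
from exoenrich.design import DesignMatrix, DesignPoint, TIME_FACTOR, VOLUME_FACTOR
from exoenrich.rsm import (
    TERMS,
    FitError,
    ModelSpec,
    RankDeficiencyError,
    _term_columns,
    anova,
    backward_eliminate,
    default_model_spec,
    fit_surface,
    predict,
    range_ratio,
)
from exoenrich.synthetic import SyntheticCCDSpec, synth_ccd


class TestModelSpec:
    def test_terms_normalized_to_canonical_order(self):
        spec = ModelSpec("y", ("x2", "intercept", "x1"))
        assert spec.terms == ("intercept", "x1", "x2")

    def test_intercept_required(self):
        with pytest.raises(FitError):
            ModelSpec("y", ("x1", "x2"))

    def test_defaults_per_response(self):
        assert default_model_spec(datasets.EXOSOME).terms == TERMS
        assert default_model_spec(datasets.CELL).terms == ("intercept", "x1", "x2")


class TestFitSurface:
    def test_predictive_columns_reproduced(self, table_design, default_fits,
                                           predictive_columns):
        """Default-form fits reproduce all printed predictive values."""
        for name, (expected, tol) in predictive_columns.items():
            np.testing.assert_allclose(
                default_fits[name].fitted, expected, atol=tol,
                err_msg=f"predictive column mismatch for {name}",
            )

    def test_exosome_quadratic_coefficients_match_normal_equations(
            self, table_design, default_fits):
        X = _term_columns(table_design.coded_array(), TERMS)
        y = table_design.response(datasets.EXOSOME)
        oracle = normal_equations_fit(X, y)
        np.testing.assert_allclose(
            default_fits[datasets.EXOSOME].coef_vector, oracle, rtol=1e-8)
        # the center-mean intercept of a quadratic CCD fit
        assert default_fits[datasets.EXOSOME].coefficients["intercept"] == pytest.approx(81.40, abs=0.005)

    def test_first_order_center_prediction_is_grand_mean(self, default_fits,
                                                         table_design):
        grand_mean = table_design.response(datasets.CELL).mean()
        assert grand_mean == pytest.approx(45700 / 13)
        center_fitted = default_fits[datasets.CELL].fitted[8:]
        np.testing.assert_allclose(center_fitted, grand_mean, rtol=1e-12)

    def test_fitted_plus_residuals_recover_observations(self, default_fits,
                                                        table_design):
        for name, fit in default_fits.items():
            np.testing.assert_allclose(
                fit.fitted + fit.residuals, table_design.response(name),
                rtol=0, atol=1e-10)

    def test_residuals_orthogonal_to_model_columns(self, default_fits,
                                                   table_design):
        for fit in default_fits.values():
            X = _term_columns(table_design.coded_array(), fit.spec.terms)
            dots = X.T @ fit.residuals
            scale = np.abs(X).sum(axis=0) * np.abs(fit.residuals).max()
            assert np.all(np.abs(dots) < 1e-6 * np.maximum(scale, 1.0))

    def test_r2_in_unit_interval(self, default_fits):
        for fit in default_fits.values():
            assert 0.0 <= fit.r2 <= 1.0
            assert fit.r2_adj <= fit.r2

    def test_zero_noise_synthetic_recovers_truth_exactly(self):
        truth = {"y": {"intercept": 80.0, "x1": 30.0, "x2": -35.0,
                       "x1:x2": -17.0, "x1^2": -3.0, "x2^2": 12.0}}
        design = synth_ccd(SyntheticCCDSpec(coefficients=truth, noise_sd={}, seed=0))
        fit = fit_surface(design, "y", ModelSpec.full_quadratic("y"))
        for term, value in truth["y"].items():
            assert fit.coefficients[term] == pytest.approx(value, abs=1e-9)
        assert np.abs(fit.residuals).max() < 1e-9

    def test_noise_orthogonal_to_model_span_leaves_coefficients_unchanged(
            self, table_design):
        X = _term_columns(table_design.coded_array(), TERMS)
        y = table_design.response(datasets.EXOSOME)
        rng = np.random.default_rng(7)
        z = rng.normal(size=y.shape)
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]  # project out model span
        perturbed = table_design.with_responses(**{datasets.EXOSOME: y + 10 * z})
        fit0 = fit_surface(table_design, datasets.EXOSOME)
        fit1 = fit_surface(perturbed, datasets.EXOSOME)
        np.testing.assert_allclose(fit1.coef_vector, fit0.coef_vector, atol=1e-8)

    def test_too_few_runs_rejected(self, table_design):
        small = DesignMatrix(
            table_design.factors, table_design.points[:5],
            responses={"y": table_design.response(datasets.EXOSOME)[:5]},
        )
        with pytest.raises(FitError, match="more runs than terms"):
            fit_surface(small, "y", ModelSpec.full_quadratic("y"))

    def test_rank_deficiency_names_collinear_terms(self):
        points = [DesignPoint(i + 1, (0.0, 0.0), (10.0, 275.0), "center")
                  for i in range(8)]
        degenerate = DesignMatrix(
            (TIME_FACTOR, VOLUME_FACTOR), points, n_center=8,
            responses={"y": np.arange(8.0)},
        )
        with pytest.raises(RankDeficiencyError, match="x1"):
            fit_surface(degenerate, "y", ModelSpec.first_order("y"))

    def test_parameter_recovery_unbiased_over_seeds(self):
        """Gaussian noise at the center-replicate scale leaves OLS unbiased."""
        truth = {datasets.EXOSOME: {"intercept": 81.4, "x1": 34.1, "x2": -35.7,
                                    "x1:x2": -17.25, "x1^2": -3.08, "x2^2": 12.18}}
        sd = {datasets.EXOSOME: 3.05}
        estimates = []
        for seed in range(1000):
            d = synth_ccd(SyntheticCCDSpec(coefficients=truth, noise_sd=sd, seed=seed))
            estimates.append(fit_surface(d, datasets.EXOSOME).coef_vector)
        estimates = np.asarray(estimates)
        truth_vec = np.array([truth[datasets.EXOSOME][t] for t in TERMS])
        sem = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert np.all(np.abs(estimates.mean(axis=0) - truth_vec) < 3 * sem + 1e-12)


class TestPredict:
    def test_design_point_predictions_match_fitted(self, default_fits,
                                                   table_design):
        fit = default_fits[datasets.EXOSOME]
        vals = predict(fit, table_design.coded_array())
        np.testing.assert_allclose(vals, fit.fitted, rtol=1e-12)

    def test_actual_unit_input_converted(self, default_fits):
        """Exact actual-unit coordinates of run 2 reproduce its fitted value
        (the printed 13.54 h / 186 uL levels are display-rounded)."""
        from exoenrich.design import TIME_FACTOR, VOLUME_FACTOR, coded_to_actual
        fit = default_fits[datasets.GLUCOSE]
        actual = (float(coded_to_actual(TIME_FACTOR, 1.0)),
                  float(coded_to_actual(VOLUME_FACTOR, -1.0)))
        run2 = predict(fit, actual, coded=False, warn_extrapolation=False)
        assert run2 == pytest.approx(36.68, abs=0.05)
        assert run2 == pytest.approx(fit.fitted[1], rel=1e-12)

    def test_optimum_region_evaluation(self, default_fits):
        """The exosome surface near the constrained optimum (~12.06 h, 150 uL)."""
        fit = default_fits[datasets.EXOSOME]
        with pytest.warns(UserWarning, match="outside the design region"):
            val = predict(fit, (12.06, 150.0), coded=False)
        assert val == pytest.approx(189.4, abs=0.5)

    def test_actual_unit_coefficients_equivalent(self, default_fits):
        fit = default_fits[datasets.EXOSOME]
        b = fit.actual_unit_coefficients()
        t, v = 11.3, 210.0
        direct = (b["intercept"] + b["x1"] * t + b["x2"] * v + b["x1:x2"] * t * v
                  + b["x1^2"] * t ** 2 + b["x2^2"] * v ** 2)
        assert direct == pytest.approx(
            float(predict(fit, (t, v), coded=False, warn_extrapolation=False)),
            rel=1e-9)


class TestAnova:
    def test_exosome_pure_error_from_center_replicates(self, default_fits,
                                                       table_design):
        table = anova(default_fits[datasets.EXOSOME], table_design)
        pe = float(table.loc[table.source == "pure_error", "SS"].iloc[0])
        assert pe == pytest.approx(37.2, abs=1e-9)

    def test_cell_pure_error(self, default_fits, table_design):
        table = anova(default_fits[datasets.CELL], table_design)
        pe = float(table.loc[table.source == "pure_error", "SS"].iloc[0])
        assert pe == pytest.approx(23000.0, abs=1e-9)

    def test_decomposition_adds_up(self, default_fits, table_design):
        for fit in default_fits.values():
            table = anova(fit, table_design).set_index("source")
            assert table.loc["model", "SS"] + table.loc["residual", "SS"] == \
                pytest.approx(table.loc["total", "SS"], rel=1e-12)
            assert table.loc["lack_of_fit", "SS"] + table.loc["pure_error", "SS"] == \
                pytest.approx(table.loc["residual", "SS"], rel=1e-9)

    def test_zero_noise_residual_ss_vanishes(self):
        truth = {"y": {"intercept": 5.0, "x1": 1.0, "x2": -2.0}}
        design = synth_ccd(SyntheticCCDSpec(coefficients=truth, noise_sd={}, seed=0))
        fit = fit_surface(design, "y", ModelSpec.first_order("y"))
        table = anova(fit, design).set_index("source")
        assert table.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_single_center_point_flagged(self):
        truth = {"y": {"intercept": 5.0, "x1": 1.0, "x2": -2.0}}
        design = synth_ccd(
            SyntheticCCDSpec(coefficients=truth, noise_sd={"y": 1.0},
                             n_center=1, seed=0))
        fit = fit_surface(design, "y", ModelSpec.first_order("y"))
        assert fit.pure_error_ss is None
        with pytest.warns(UserWarning, match="pure error unavailable"):
            anova(fit, design)


class TestRangeRatio:
    @pytest.mark.parametrize("response, expected", [
        (datasets.EXOSOME, 178 / 27),
        (datasets.CELL, 4000 / 2700),
        (datasets.GLUCOSE, 99 / 35.2),
    ])
    def test_experimental_column_ratios(self, table_design, response, expected):
        assert range_ratio(table_design, response)["ratio"] == pytest.approx(expected)

    def test_constant_column_gives_unity(self, table_design):
        d = table_design.with_responses(const=np.full(13, 42.0))
        assert range_ratio(d, "const")["ratio"] == 1.0

    def test_nonpositive_min_rejected(self, table_design):
        d = table_design.with_responses(signed=np.linspace(-1, 1, 13))
        with pytest.raises(ValueError, match="undefined"):
            range_ratio(d, "signed")


class TestBackwardElimination:
    def test_keeps_intercept_and_returns_valid_fit(self, table_design):
        fit = backward_eliminate(table_design, datasets.CELL)
        assert "intercept" in fit.spec.terms
        assert set(fit.spec.terms) <= set(TERMS)

    def test_strong_terms_survive(self, table_design):
        fit = backward_eliminate(table_design, datasets.EXOSOME)
        assert {"x1", "x2"} <= set(fit.spec.terms)
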