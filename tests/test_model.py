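"""OLS quadratic fit: oracle equivalence, invariances, predictions."""

import numpy as np
import pytest

import shelfrsm as s
from shelfrsm.model import (
    ExtrapolationWarning,
    SingularDesignError,
    coefficients_report,
    fit_quadratic,
    model_matrix,
)
from shelfrsm.reference import PREDICTED_COLUMN_ATOL
from tests.conftest import ALL_RESPONSES

#: Published predicted columns for the bundled designs, run order 1-13.
PREDICTED = {
    ("OLPR", "ambient"): [3.00, 4.32, 3.31, 7.48, 8.81, 7.81, 7.14, 8.47,
                          7.48, 3.00, 3.00, 3.00, 3.00],
    ("SCG", "ambient"): [3.03, 3.77, 3.77, 7.81, 7.95, 7.15, 7.04, 6.58,
                         4.98, 3.03, 3.03, 3.03, 3.03],
    ("OLPR_SCG", "ambient"): [3.03, 4.00, 4.78, 7.78, 8.51, 9.11, 6.90,
                              7.39, 7.81, 3.03, 3.03, 3.03, 3.03],
    ("OLPR", "cold_4C"): [5.50, 7.46, 6.36, 20.58, 22.64, 21.68, 21.64,
                          23.80, 22.96, 5.50, 5.50, 5.50, 5.50],
    ("SCG", "cold_4C"): [5.52, 6.89, 6.31, 20.58, 22.03, 21.63, 21.56,
                         23.18, 22.96, 5.52, 5.52, 5.52, 5.52],
    ("OLPR_SCG", "cold_4C"): [5.51, 7.20, 7.85, 20.75, 23.09, 24.36, 21.40,
                              24.41, 26.29, 5.51, 5.51, 5.51, 5.51],
}


def normal_equations_fit(design):
    """Independent oracle: solve the 6x6 normal equations directly."""
    A = model_matrix(design.coded_settings())
    y = design.responses
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitAgainstOracles:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_qr_solution_equals_normal_equations(self, fits, key):
        _, fit, _ = fits[key]
        assert np.allclose(
            fit.model.coefficient_vector(),
            normal_equations_fit(fit.design),
            atol=1e-9,
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_noiseless_surface_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 5, size=6)
        layout = s.shelf_life_design("OLPR")
        design = layout.with_responses(
            np.clip(model_matrix(layout.coded_settings()) @ beta, 0, None)
        )
        keep = model_matrix(layout.coded_settings()) @ beta
        if np.any(keep < 0):  # clipping would break exact interpolation
            design = layout.with_responses(keep - keep.min())
            beta = beta.copy()
            beta[0] -= keep.min()
        fit = fit_quadratic(design)
        assert np.allclose(fit.model.coefficient_vector(), beta, atol=1e-8)

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_residuals_orthogonal_to_model_columns(self, fits, key):
        design, fit, _ = fits[key]
        A = model_matrix(design.coded_settings())
        assert np.allclose(A.T @ fit.residuals, 0.0, atol=1e-9)

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_leverages_sum_to_p(self, fits, key):
        _, fit, _ = fits[key]
        assert fit.leverages.sum() == pytest.approx(6.0, abs=1e-9)
        assert np.all((fit.leverages > 0) & (fit.leverages < 1))


class TestFittedValues:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_fitted_match_published_predicted_columns(self, fits, key):
        _, fit, _ = fits[key]
        assert np.allclose(
            fit.fitted, PREDICTED[key], atol=PREDICTED_COLUMN_ATOL
        )

    def test_spot_predictions_on_ambient_fit(self, m1_ambient):
        _, fit, _ = m1_ambient
        pred = fit.model.predict({"packaging": "NONE", "rate": 0.3})
        assert pred == pytest.approx(4.32, abs=0.05)
        pred = fit.model.predict({"packaging": "PBP", "rate": 0.3})
        assert pred == pytest.approx(8.81, abs=0.05)

    def test_spot_predictions_on_cold_fit(self, fits):
        _, fit, _ = fits[("OLPR", "cold_4C")]
        assert fit.model.predict({"packaging": "NONE", "rate": 0.3}) == (
            pytest.approx(7.46, abs=0.05)
        )

    def test_prediction_at_coded_origin_is_intercept(self, m1_ambient):
        _, fit, _ = m1_ambient
        assert fit.model.predict_coded([[0.0, 0.0]])[0] == pytest.approx(
            fit.model.beta0
        )

    def test_extrapolation_warns_but_evaluates(self, m1_ambient):
        _, fit, _ = m1_ambient
        with pytest.warns(ExtrapolationWarning):
            v = fit.model.predict({"packaging": "PBP", "rate": 0.9})
        assert np.isfinite(v)


class TestCodingInvariance:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_fitted_values_nearly_invariant_to_rate_coding(self, key):
        scheme, temp = key
        fl = fit_quadratic(s.load_shelf_life(scheme, temp, "level"))
        fr = fit_quadratic(s.load_shelf_life(scheme, temp, "range"))
        # only the interaction column differs between the codings
        assert np.allclose(fl.fitted, fr.fitted, atol=0.1)

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_exact_invariance_without_interaction_column(self, key):
        scheme, temp = key
        dl = s.load_shelf_life(scheme, temp, "level")
        dr = s.load_shelf_life(scheme, temp, "range")
        keep = [0, 1, 2, 4, 5]  # drop the interaction column
        for da, db in [(dl, dr)]:
            Aa = model_matrix(da.coded_settings())[:, keep]
            Ab = model_matrix(db.coded_settings())[:, keep]
            ya = da.responses
            fa = Aa @ np.linalg.lstsq(Aa, ya, rcond=None)[0]
            fb = Ab @ np.linalg.lstsq(Ab, ya, rcond=None)[0]
            assert np.allclose(fa, fb, atol=1e-9)


class TestCoefficientsReport:
    def test_six_terms_interaction_smallest_for_ambient_fit(self, m1_ambient):
        _, fit, _ = m1_ambient
        report = coefficients_report(fit.model)
        assert len(report) == 6
        mags = dict(zip(report["term"], report["coefficient"].abs()))
        inter = mags["packaging:rate"]
        assert inter == min(v for k, v in mags.items() if k != "intercept")

    def test_pure_quadratic_response_recovers_structure(self):
        layout = s.shelf_life_design("OLPR")
        coded = layout.coded_settings()
        design = layout.with_responses(coded[:, 1] ** 2)
        fit = fit_quadratic(design)
        assert fit.model.beta_quadratic["rate"] == pytest.approx(1.0, abs=1e-10)
        for v in list(fit.model.beta_linear.values()) + list(
            fit.model.beta_interaction.values()
        ):
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_report_invariant_under_run_reordering(self, m1_ambient):
        design, fit, _ = m1_ambient
        shuffled = s.DesignMatrix(
            design.factors, list(reversed(design.runs)), design.response_name
        )
        fit2 = fit_quadratic(shuffled)
        a = coefficients_report(fit.model)
        b = coefficients_report(fit2.model)
        assert np.allclose(a["coefficient"], b["coefficient"], atol=1e-10)


class TestErrorsAndRoundTrip:
    def test_singular_design_names_collinear_columns(self):
        layout = s.shelf_life_design("OLPR")
        # collapse the rate axis: only the control column of the grid
        runs = [r for r in layout.runs if r.settings["rate"] == 0.0]
        design = s.DesignMatrix(layout.factors, runs)
        design = design.with_responses(np.arange(len(runs), dtype=float) + 1)
        with pytest.raises(SingularDesignError, match="rate"):
            fit_quadratic(design)

    def test_too_few_runs_rejected(self):
        layout = s.shelf_life_design("OLPR")
        small = s.DesignMatrix(layout.factors, layout.runs[:6])
        small = small.with_responses(np.ones(6))
        with pytest.raises(ValueError, match="at least"):
            fit_quadratic(small)

    def test_model_json_round_trip(self, m1_ambient, tmp_path):
        _, fit, _ = m1_ambient
        path = tmp_path / "model.json"
        fit.model.to_json(path)
        back = s.QuadraticModel.from_json(path)
        assert np.allclose(
            back.coefficient_vector(), fit.model.coefficient_vector()
        )
        assert back.residual_dof == fit.model.residual_dof
        for settings in ({"packaging": "VBP", "rate": 0.5},):
            assert back.predict(settings) == pytest.approx(
                fit.model.predict(settings)
            )
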