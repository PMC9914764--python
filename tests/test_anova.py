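"""ANOVA decomposition, lack of fit, PRESS and the R2 family."""

import numpy as np
import pytest
from scipy import stats

import shelfrsm as s
from shelfrsm.anova import adequate_precision, anova_table, format_p, lack_of_fit, press
from shelfrsm.model import fit_quadratic, model_matrix
from shelfrsm.reference import (
    ADEQ_RTOL,
    LOF_F_ATOL,
    PRED_R2_ATOL,
    R2_FAMILY_ATOL,
    REFERENCE_MODEL_STATS,
    RESIDUAL_SCALE_ATOL,
    SS_F_RTOL,
)
from shelfrsm.synthetic import SyntheticConfig, simulate_design
from tests.conftest import ALL_RESPONSES


def loo_press(design):
    """Independent oracle: refit with each run left out."""
    total = 0.0
    for i in range(len(design.runs)):
        runs = [r for j, r in enumerate(design.runs) if j != i]
        sub = s.DesignMatrix(design.factors, runs, design.response_name)
        model = fit_quadratic(sub).model
        coded = design.coded_settings()[i : i + 1]
        pred = model.predict_coded(coded)[0]
        total += (design.runs[i].response - pred) ** 2
    return total


class TestConservation:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_ss_partitions_on_bundled_fits(self, fits, key):
        _, _, report = fits[key]
        ss = {r.term: r.sum_sq for r in report.rows}
        assert ss["Model"] + ss["Residual"] == pytest.approx(
            ss["Total"], rel=1e-9
        )
        assert ss["LackOfFit"] + ss["PureError"] == pytest.approx(
            ss["Residual"], rel=1e-9
        )
        assert all(v >= 0 for v in ss.values())

    def test_ss_partitions_on_random_synthetic_designs(self):
        layout = s.shelf_life_design("OLPR")
        for seed in range(200):
            rng = np.random.default_rng(seed)
            config = SyntheticConfig(
                true_beta=tuple(rng.normal(10, 3, size=6)),
                noise_sd=0.5,
                seed=seed,
            )
            design = simulate_design(config, layout)
            fit = fit_quadratic(design)
            report = anova_table(design, fit)
            ss = {r.term: r.sum_sq for r in report.rows}
            assert ss["Model"] + ss["Residual"] == pytest.approx(
                ss["Total"], rel=1e-9, abs=1e-9
            )
            assert ss["LackOfFit"] + ss["PureError"] == pytest.approx(
                ss["Residual"], rel=1e-9, abs=1e-9
            )

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_dof_bookkeeping(self, fits, key):
        _, _, report = fits[key]
        dof = {r.term: r.dof for r in report.rows}
        assert dof["Model"] == 5
        assert dof["Residual"] == 7
        assert dof["PureError"] == 4
        assert dof["LackOfFit"] == 3
        assert dof["Total"] == 12


class TestPress:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_shortcut_equals_leave_one_out_refit(self, fits, key):
        design, fit, report = fits[key]
        assert report.press == pytest.approx(loo_press(design), rel=1e-8)

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_press_at_least_residual_ss(self, fits, key):
        _, fit, report = fits[key]
        assert report.press >= fit.residual_ss

    def test_unit_leverage_rejected(self, m1_ambient):
        # a point that determines its own fit cannot be cross-validated
        design, fit, _ = m1_ambient
        import copy

        broken = copy.copy(fit)
        broken.leverages = fit.leverages.copy()
        broken.leverages[3] = 1.0
        with pytest.raises(ValueError, match="leverage"):
            press(design, broken)


class TestR2Family:
    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_r2_ordering(self, fits, key):
        _, _, report = fits[key]
        assert report.pred_r2 <= report.adj_r2 <= report.r2 <= 1.0

    def test_perfect_fit_gives_unit_r2(self):
        layout = s.shelf_life_design("OLPR")
        config = SyntheticConfig(noise_sd=0.0, seed=1)
        design = simulate_design(config, layout)
        fit = fit_quadratic(design)
        report = anova_table(design, fit)
        assert report.r2 == pytest.approx(1.0, abs=1e-12)
        assert report.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_rejected(self):
        layout = s.shelf_life_design("OLPR")
        design = layout.with_responses(np.full(13, 5.0))
        fit = fit_quadratic(design)
        with pytest.raises(ValueError, match="undefined"):
            anova_table(design, fit)


class TestLackOfFit:
    def test_pure_error_from_control_replicates(self, m1_ambient):
        design, fit, _ = m1_ambient
        _, pure = lack_of_fit(design, fit)
        # five control replicates 3.00/3.10/2.90/3.20/2.80, mean 3.00
        assert pure["sum_sq"] == pytest.approx(0.10, abs=1e-9)
        assert pure["dof"] == 4

    def test_pure_error_invariant_to_model_specification(self, m1_ambient):
        # shifting the non-replicated responses changes the fitted model
        # but cannot change within-group scatter
        design, fit, _ = m1_ambient
        _, pure_full = lack_of_fit(design, fit)
        shifted = design.responses.copy()
        shifted[3:9] += 2.5  # the six packed runs, all singleton groups
        other = design.with_responses(shifted)
        fit_other = fit_quadratic(other)
        _, pure_other = lack_of_fit(other, fit_other)
        assert pure_other["sum_sq"] == pytest.approx(pure_full["sum_sq"])
        assert pure_other["dof"] == pure_full["dof"]

    def test_no_replicates_rejected(self):
        layout = s.shelf_life_design("OLPR")
        runs = layout.runs[:9]  # distinct grid points only
        design = s.DesignMatrix(layout.factors, runs)
        design = design.with_responses(np.arange(9, dtype=float) + 1)
        fit = fit_quadratic(design)
        with pytest.raises(ValueError, match="replicated"):
            lack_of_fit(design, fit)


class TestPValues:
    def test_p_decreases_in_f_at_fixed_dof(self):
        fvals = np.linspace(0.1, 50, 40)
        ps = [stats.f.sf(f, 3, 4) for f in fvals]
        assert np.all(np.diff(ps) < 0)

    def test_p_rendering_dialect(self):
        assert format_p(0.00005) == "<0.0001"
        assert format_p(0.0035) == "0.0035"
        assert format_p(0.9712) == "0.9712"


class TestPartialVsSequential:
    def test_orthogonal_columns_give_equal_partial_and_sequential(self):
        # On the full 3x3 grid the linear and interaction columns are
        # orthogonal to every other model column, so both SS types agree
        # for them (the correlated quadratic columns differ).
        layout = s.shelf_life_design("OLPR")
        runs = layout.runs[:9]
        design = s.DesignMatrix(layout.factors, runs)
        rng = np.random.default_rng(7)
        design = design.with_responses(rng.uniform(2, 10, size=9))
        fit = fit_quadratic(design)
        part = anova_table(design, fit, ss_type="partial")
        seq = anova_table(design, fit, ss_type="sequential")
        for term in ("packaging", "rate", "packaging:rate"):
            assert part.row(term).sum_sq == pytest.approx(
                seq.row(term).sum_sq, rel=1e-9, abs=1e-9
            )


class TestGoldenModelStatistics:
    """Freshly computed summaries against the published reference values."""

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_r2_family_matches_reference(self, fits, key):
        _, _, report = fits[key]
        ref = REFERENCE_MODEL_STATS[key]
        assert report.r2 == pytest.approx(ref["r2"], abs=R2_FAMILY_ATOL)
        assert report.adj_r2 == pytest.approx(
            ref["adj_r2"], abs=R2_FAMILY_ATOL
        )
        # the SCG cold-storage table prints r2 0.9999 with adj 0.9983, an
        # internally inconsistent pair; its exact r2 is checked above via
        # the shared tolerance and its adjusted value here
        assert report.pred_r2 == pytest.approx(
            ref["pred_r2"], abs=PRED_R2_ATOL
        )

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_model_and_residual_ss_match_reference(self, fits, key):
        _, _, report = fits[key]
        ref = REFERENCE_MODEL_STATS[key]
        assert report.row("Model").sum_sq == pytest.approx(
            ref["model_ss"], rel=SS_F_RTOL
        )
        assert report.row("Residual").sum_sq == pytest.approx(
            ref["residual_ss"], rel=SS_F_RTOL, abs=RESIDUAL_SCALE_ATOL
        )
        # the F denominator is residual-scale, so the ratio inherits the
        # residual-scale rounding error in relative form
        f_rtol = SS_F_RTOL + RESIDUAL_SCALE_ATOL / ref["residual_ss"]
        assert report.row("Model").F == pytest.approx(
            ref["model_f"], rel=f_rtol
        )

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_press_and_adequate_precision_match_reference(self, fits, key):
        _, fit, report = fits[key]
        ref = REFERENCE_MODEL_STATS[key]
        assert report.press == pytest.approx(
            ref["press"], rel=SS_F_RTOL, abs=RESIDUAL_SCALE_ATOL
        )
        assert report.adeq_precision == pytest.approx(
            ref["adeq_precision"], rel=ADEQ_RTOL
        )

    @pytest.mark.parametrize("key", ALL_RESPONSES)
    def test_lack_of_fit_f_matches_reference(self, fits, key):
        _, _, report = fits[key]
        ref = REFERENCE_MODEL_STATS[key]
        got = report.row("LackOfFit").F
        assert got == pytest.approx(
            ref["lof_f"], rel=SS_F_RTOL, abs=LOF_F_ATOL
        )


class TestAdequatePrecision:
    def test_constant_fitted_surface_gives_zero(self, m1_ambient):
        import copy

        _, fit, _ = m1_ambient
        flat = copy.copy(fit)
        flat.fitted = np.full_like(fit.fitted, 5.0)
        assert adequate_precision(flat) == 0.0
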