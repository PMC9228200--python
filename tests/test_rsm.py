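"""Quadratic response-surface fitting, prediction, diagnostics, comparison."""

import numpy as np
import pandas as pd
import pytest

from medopt import (
    SyntheticExperimentSpec,
    adjusted_r2,
    compare_models,
    fit_quadratic,
    model_anova,
    predict_response,
    response_gradient,
    simulate_bbd_responses,
    surface_slice,
)
from medopt import reference as ref
from medopt.errors import RangeError, SingularFitError, ValidationError
from medopt.rsm import QuadraticModel

OPTIMUM = [5.0, 0.0, 3.77, 0.5]


class TestPredictResponse:
    def test_reference_surfaces_at_reported_optimum(self):
        """The two published coefficient sets predict 30.66 / 27.84 mm."""
        assert predict_response(ref.SA2BSS_MODEL, OPTIMUM) == pytest.approx(30.66, abs=0.005)
        assert predict_response(ref.PA2DSS_MODEL, OPTIMUM) == pytest.approx(27.84, abs=0.005)

    def test_intercept_only_model_is_constant(self):
        names = ("a", "b")
        m = QuadraticModel(
            factor_names=names,
            intercept=4.5,
            linear={n: 0.0 for n in names},
            interaction={("a", "b"): 0.0},
            quadratic={n: 0.0 for n in names},
        )
        assert predict_response(m, [1.0, 2.0]) == 4.5
        assert predict_response(m, [-3.0, 7.0]) == 4.5

    def test_extrapolation_guard(self):
        with pytest.raises(RangeError, match="cellulose"):
            predict_response(ref.SA2BSS_MODEL, [50.0, 0.0, 2.5, 2.5])
        # explicit opt-in allows it
        predict_response(ref.SA2BSS_MODEL, [50.0, 0.0, 2.5, 2.5], extrapolate=True)

    def test_gradient_matches_finite_differences(self):
        point = [12.0, 1.0, 3.0, 2.0]
        grad = response_gradient(ref.SA2BSS_MODEL, point)
        for i, name in enumerate(ref.SA2BSS_MODEL.factor_names):
            stepped = list(point)
            stepped[i] += 1e-6
            fd = (
                predict_response(ref.SA2BSS_MODEL, stepped, extrapolate=True)
                - predict_response(ref.SA2BSS_MODEL, point, extrapolate=True)
            ) / 1e-6
            assert grad[name] == pytest.approx(fd, abs=1e-4)


class TestFitQuadratic:
    def test_noise_free_fit_recovers_coefficients(self, noise_free_design):
        """OLS on exact surface data returns the generating coefficients."""
        for resp, truth in (("SA2BSS", ref.SA2BSS_MODEL), ("PA2DSS", ref.PA2DSS_MODEL)):
            model, diag = fit_quadratic(noise_free_design, resp)
            est, true = model.coefficient_vector(), truth.coefficient_vector()
            np.testing.assert_allclose(est, true, rtol=1e-6, atol=1e-9)
            assert diag.r2 == pytest.approx(1.0, abs=1e-12)
            assert diag.df_residual == 12

    def test_hat_matrix_consistency(self, noisy_design):
        """Model predictions at the design points equal OLS fitted values."""
        model, diag = fit_quadratic(noisy_design, "SA2BSS")
        from medopt.rsm import quadratic_basis

        basis = quadratic_basis(noisy_design.natural, noisy_design.factor_names)
        fitted = basis.to_numpy() @ model.coefficient_vector()
        preds = [
            predict_response(model, row)
            for row in noisy_design.natural.to_numpy()
        ]
        np.testing.assert_allclose(preds, fitted, rtol=1e-9)

    def test_coded_and_natural_fits_predict_identically(self, noisy_design):
        """Units only reparameterize the basis; predictions must agree."""
        nat, _ = fit_quadratic(noisy_design, "SA2BSS", "natural")
        cod, _ = fit_quadratic(noisy_design, "SA2BSS", "coded")
        assert not np.allclose(nat.coefficient_vector(), cod.coefficient_vector())
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.uniform(-1, 1, 4)
            x = [f.center + zi * f.half_range for f, zi in zip(ref.FACTORS, z)]
            assert predict_response(cod, z) == pytest.approx(
                predict_response(nat, x), rel=1e-9
            )

    def test_insufficient_runs_rejected(self, noise_free_design):
        from dataclasses import replace

        small = replace(
            noise_free_design,
            coded=noise_free_design.coded.iloc[:14],
            natural=noise_free_design.natural.iloc[:14],
            run_order=noise_free_design.run_order[:14],
            responses=noise_free_design.responses.iloc[:14],
        )
        with pytest.raises(ValidationError, match="insufficient"):
            fit_quadratic(small, "SA2BSS")

    def test_rank_deficient_design_reports_aliased_terms(self, noise_free_design):
        """Collapsing a factor to one level aliases its terms."""
        from dataclasses import replace

        nat = noise_free_design.natural.copy()
        nat["urea"] = 2.5
        cod = noise_free_design.coded.copy()
        cod["urea"] = 0.0
        degenerate = replace(noise_free_design, natural=nat, coded=cod)
        with pytest.raises(SingularFitError, match="urea"):
            fit_quadratic(degenerate, "SA2BSS")

    def test_coefficient_recovery_unbiased_under_noise(self, bbd27):
        """Mean of 200 noisy-fit estimates stays within 3 SE of truth."""
        truth = ref.SA2BSS_MODEL.coefficient_vector()
        estimates = []
        for seed in range(200):
            d = simulate_bbd_responses(
                SyntheticExperimentSpec(
                    design=bbd27,
                    models={"SA2BSS": ref.SA2BSS_MODEL},
                    noise_sd=0.3,
                    seed=seed,
                )
            )
            model, _ = fit_quadratic(d, "SA2BSS")
            estimates.append(model.coefficient_vector())
        est = np.asarray(estimates)
        mean = est.mean(axis=0)
        se_of_mean = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(mean - truth) <= 3.0 * se_of_mean + 1e-12)


class TestModelAnova:
    def test_noise_free_residual_is_zero(self, noise_free_design):
        model, _ = fit_quadratic(noise_free_design, "PA2DSS")
        aov = model_anova(model, noise_free_design, "PA2DSS")
        assert aov.row("residual")["SS"] <= 1e-9 * aov.row("total")["SS"]

    def test_ss_additivity(self, noisy_design):
        model, _ = fit_quadratic(noisy_design, "SA2BSS")
        aov = model_anova(model, noisy_design, "SA2BSS")
        assert aov.row("model")["SS"] + aov.row("residual")["SS"] == pytest.approx(
            aov.row("total")["SS"], rel=1e-9
        )

    def test_noisy_fit_r2_in_published_regime(self, noisy_design):
        """sigma = 0.5 mm puts R^2 in the 0.9-1.0 band of the study."""
        for resp in ("SA2BSS", "PA2DSS"):
            model, diag = fit_quadratic(noisy_design, resp)
            assert 0.9 <= diag.r2 <= 1.0

    def test_uncorrected_mode_inflates_model_ss(self, noisy_design):
        model, _ = fit_quadratic(noisy_design, "SA2BSS")
        corrected = model_anova(model, noisy_design, "SA2BSS")
        raw = model_anova(model, noisy_design, "SA2BSS", uncorrected=True)
        assert raw.row("model")["SS"] > corrected.row("model")["SS"]


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,expected", [(0.96, 0.91), (0.95, 0.89)], ids=["SA2BSS", "PA2DSS"]
    )
    def test_published_bridge_values(self, r2, expected):
        """R^2 of 0.96/0.95 on 27 runs, 15 terms give adjusted 0.91/0.89."""
        assert adjusted_r2(r2, 27, 15) == pytest.approx(expected, abs=0.005)

    def test_perfect_fit_stays_perfect(self):
        assert adjusted_r2(1.0, 27, 15) == 1.0
        assert adjusted_r2(1.0, 20, 5) == 1.0

    def test_undefined_when_saturated(self):
        with pytest.raises(ValidationError):
            adjusted_r2(0.9, 15, 15)


class TestSurfaceSlice:
    def test_consistency_with_pointwise_prediction(self):
        grid = surface_slice(ref.SA2BSS_MODEL, ("urea", "ammonium_sulfate"), grid=5)
        assert len(grid) == 25
        for _, row in grid.iterrows():
            point = {
                "cellulose": 20.0,
                "dipotassium_phosphate": 2.5,
                "urea": row["urea"],
                "ammonium_sulfate": row["ammonium_sulfate"],
            }
            assert row["SA2BSS"] == pytest.approx(
                predict_response(ref.SA2BSS_MODEL, point, extrapolate=True)
            )

    def test_center_slice_maximum_sits_on_boundary(self):
        """The urea x ammonium-sulfate center slice peaks on the rectangle edge."""
        grid = surface_slice(ref.SA2BSS_MODEL, ("urea", "ammonium_sulfate"), grid=41)
        best = grid.loc[grid["SA2BSS"].idxmax()]
        on_edge = (
            best["urea"] in (0.0, 5.0)
            or best["ammonium_sulfate"] in (0.0, 5.0)
        )
        assert on_edge

    def test_unknown_factor_rejected(self):
        with pytest.raises(KeyError):
            surface_slice(ref.SA2BSS_MODEL, ("urea", "nope"))


class TestCompareModels:
    def test_rsm_selected_over_ann(self):
        table = compare_models([("RSM", 0.91), ("ANN", 0.83)])
        assert table.iloc[0]["model"] == "RSM"
        assert bool(table.iloc[0]["selected"]) and not bool(table.iloc[1]["selected"])
        table2 = compare_models([("ANN", 0.81), ("RSM", 0.89)])
        assert table2.iloc[0]["model"] == "RSM"

    def test_ties_all_flagged_stable_order(self):
        table = compare_models([("b", 0.9), ("a", 0.9), ("c", 0.1)])
        assert list(table["model"][:2]) == ["b", "a"]
        assert table["selected"][:2].all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compare_models([])
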