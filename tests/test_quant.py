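"""PLS calibration, cross-validation, metrics and external validation."""

import numpy as np
import pytest

from rootspec import (
    NoiseModel,
    PreprocessSpec,
    SpectralWindows,
    apply_pipeline,
    compute_metrics,
    external_validation,
    fit_pls,
    loocv,
    metrics_table,
    optimize_model,
    predict,
    rpd_class,
)
from rootspec.errors import ContractError
from rootspec.simulate import design_2species, simulate_mixture_set


def two_species_data(seed=1, replicates=2, grid=None, noise=None):
    design = design_2species(10.0)
    spectra, Y = simulate_mixture_set(
        design, replicates, noise=noise or NoiseModel.ground(seed), grid=grid
    )
    return spectra, Y


class TestFitPredict:
    def test_exact_linear_recovery(self, rng):
        X = rng.normal(size=(12, 5))
        B = rng.normal(size=(5, 2))
        Y = 40.0 + X @ B
        model = fit_pls(X, Y, n_components=5)
        np.testing.assert_allclose(predict(model, X), Y, atol=1e-6)

    def test_one_component_matches_hand_computed_projection(self):
        """1-latent-variable NIPALS on a 3x2 mean-centered example reduces to
        regression on the projection onto the dominant covariance direction;
        the expected values below are the closed-form solution."""
        X = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        y = np.array([[10.0], [20.0], [30.0]])
        # centered X has a single nonzero column: w = (1, 0), scores t = Xc w,
        # q = (Yc.t)/(t.t) = 10, predictions = ybar + t*q = exact
        model = fit_pls(X, y, n_components=1)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)
        np.testing.assert_allclose(model.coef.ravel(), [10.0, 0.0], atol=1e-8)

    def test_duplicating_rows_leaves_coefficients_unchanged(self, rng):
        X = rng.normal(size=(8, 4))
        Y = rng.normal(size=(8, 2))
        a = fit_pls(X, Y, 3)
        b = fit_pls(np.vstack([X, X]), np.vstack([Y, Y]), 3)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-8)

    def test_mean_spectrum_predicts_mean_composition(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.uniform(0, 100, size=(10, 2))
        model = fit_pls(X, Y, 3)
        np.testing.assert_allclose(
            predict(model, X.mean(axis=0)), Y.mean(axis=0)[None, :], atol=1e-8
        )

    def test_excessive_components_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 1))
        with pytest.raises(ContractError):
            fit_pls(X, Y, 5)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_pls(rng.normal(size=(6, 4)), rng.normal(size=(6, 1)), 2)
        with pytest.raises(ContractError):
            predict(model, rng.normal(size=(2, 7)))

    def test_noise_free_mixture_fractions_recovered(self, coarse_grid):
        """k noise-free additive mixtures have spectral rank k-1 after
        centering; PLS at k-1 components recovers fractions near-exactly."""
        spectra, Y = two_species_data(noise=NoiseModel.silent(), grid=coarse_grid,
                                      replicates=1)
        X, _, _ = apply_pipeline(spectra, PreprocessSpec(steps=()))
        model = fit_pls(X, Y.to_numpy(), n_components=1, species=list(Y.columns))
        preds = predict(model, X)
        np.testing.assert_allclose(preds, Y.to_numpy(), atol=0.1)

    def test_closure_preserved_by_predictions(self, coarse_grid):
        spectra, Y = two_species_data(grid=coarse_grid)
        X, _, _ = apply_pipeline(spectra, PreprocessSpec())
        model = fit_pls(X, Y.to_numpy(), 2, species=list(Y.columns))
        preds = predict(model, X)
        np.testing.assert_allclose(preds.sum(axis=1), 100.0, atol=1e-6)

    def test_model_json_round_trip(self, tmp_path, rng):
        from rootspec.quant import PLSModel

        X = rng.normal(size=(8, 5))
        Y = rng.uniform(0, 100, size=(8, 2))
        model = fit_pls(X, Y, 2, species=("a", "b"))
        path = model.to_json(tmp_path / "model.json")
        back = PLSModel.from_json(path)
        np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)


class TestLoocv:
    def test_noise_free_linear_data_has_near_zero_rmsecv(self, rng):
        X = rng.normal(size=(10, 6))
        Y = 50.0 + X @ rng.normal(size=(6, 1))
        result = loocv(X, Y, max_components=6)
        assert result.table["rmsecv_mean"].min() < 1e-6

    def test_matches_manual_fold_oracle(self, rng):
        X = rng.normal(size=(4, 3))
        Y = rng.uniform(10, 90, size=(4, 1))
        result = loocv(X, Y, max_components=2)
        for c in (1, 2):
            manual = np.empty_like(Y)
            for i in range(4):
                keep = [j for j in range(4) if j != i]
                m = fit_pls(X[keep], Y[keep], c)
                manual[i] = predict(m, X[i])
            rmse = float(np.sqrt(np.mean((manual - Y) ** 2)))
            assert result.table.loc[c, "rmsecv_mean"] == pytest.approx(rmse, abs=1e-9)

    def test_sample_order_invariant(self, rng):
        X = rng.normal(size=(8, 5))
        Y = rng.uniform(0, 100, size=(8, 2))
        a = loocv(X, Y, 3)
        perm = rng.permutation(8)
        b = loocv(X[perm], Y[perm], 3)
        np.testing.assert_allclose(
            a.table["rmsecv_mean"], b.table["rmsecv_mean"], atol=1e-9
        )

    def test_infeasible_max_components_reduced_with_warning(self, rng):
        X = rng.normal(size=(5, 10))
        Y = rng.uniform(0, 100, size=(5, 1))
        with pytest.warns(UserWarning, match="reduced"):
            result = loocv(X, Y, max_components=8)
        assert result.table.index.max() == 3  # n - 2

    def test_components_beyond_effective_rank_not_selected(self):
        # X has rank 1: the second latent variable has nothing to extract
        X = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        Y = np.array([[10.0], [20.0], [30.0], [40.0]])
        result = loocv(X, Y, 2)
        assert result.selected == 1
        assert not np.isfinite(result.table.loc[2, "rmsecv_mean"])


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        m = compute_metrics(y, y, "calibration")
        assert m.rmse == 0.0 and m.bias == 0.0 and m.r2 == 1.0
        assert np.isinf(m.rpd)

    @pytest.mark.parametrize(
        "rpd,expected",
        [(12.1, "excellent"), (8.73, "good"), (3.11, "sufficient"),
         (3.0, "insufficient"), (1.0, "insufficient"), (10.0, "good"),
         (5.0, "sufficient")],
    )
    def test_rpd_classification(self, rpd, expected):
        assert rpd_class(rpd) == expected

    def test_rpd_uses_sample_sd_over_rmse(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        yhat = y + np.array([1.0, -1.0, 1.0, -1.0])
        m = compute_metrics(y, yhat)
        assert m.rmse == pytest.approx(1.0)
        assert m.rpd == pytest.approx(np.std(y, ddof=1) / 1.0)
        assert m.bias == pytest.approx(0.0)

    def test_constant_reference_rejected(self):
        with pytest.raises(ContractError):
            compute_metrics(np.full(4, 50.0), np.arange(4.0))

    def test_bias_bounded_by_rmse(self, rng):
        y = rng.uniform(0, 100, 20)
        yhat = y + rng.normal(0, 3, 20)
        m = compute_metrics(y, yhat)
        assert abs(m.bias) <= m.rmse

    def test_metric_order_invariance(self, rng):
        y = rng.uniform(0, 100, 15)
        yhat = y + rng.normal(0, 2, 15)
        perm = rng.permutation(15)
        a = compute_metrics(y, yhat)
        b = compute_metrics(y[perm], yhat[perm])
        assert a.rmse == pytest.approx(b.rmse) and a.r2 == pytest.approx(b.r2)


class TestClosureSymmetry:
    def test_two_species_rmse_equal_and_bias_opposite(self, coarse_grid):
        """With compositions closed to 100%, the joint two-response PLS gives
        mirrored errors: identical RMSE, biases equal and opposite."""
        spectra, Y = two_species_data(seed=4, grid=coarse_grid,
                                      noise=NoiseModel.dried(4))
        X, _, _ = apply_pipeline(spectra, PreprocessSpec())
        result = loocv(X, Y.to_numpy(), 5, species=list(Y.columns))
        m1, m2 = result.metrics["maize"], result.metrics["wild_oat"]
        assert m1.rmse == pytest.approx(m2.rmse, abs=1e-9)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-9)


class TestOptimize:
    def test_single_candidate_returned(self, coarse_grid):
        spectra, Y = two_species_data(grid=coarse_grid)
        spec = PreprocessSpec()
        result = optimize_model(spectra, Y.to_numpy(), [spec], 3,
                                species=list(Y.columns))
        assert result.best_spec is spec
        assert len(result.leaderboard) == 3

    def test_normalization_beats_raw_under_scale_noise(self, coarse_grid):
        noise = NoiseModel(additive_sd=0.002, amplitude_cv=0.02,
                           baseline_drift_sd=0.0, scale_sd=0.3, seed=6)
        spectra, Y = two_species_data(grid=coarse_grid, noise=noise, replicates=3)
        lo, hi = coarse_grid.span
        raw = PreprocessSpec(steps=(), windows=SpectralWindows([(lo, hi)]))
        vn = PreprocessSpec(steps=("vector_normalize",),
                            windows=SpectralWindows([(lo, hi)]))
        result = optimize_model(spectra, Y.to_numpy(), [raw, vn], 4,
                                species=list(Y.columns))
        assert result.best_spec_index == 1

    def test_leaderboard_covers_full_grid(self, coarse_grid):
        spectra, Y = two_species_data(grid=coarse_grid)
        specs = [PreprocessSpec(), PreprocessSpec(steps=("vector_normalize",))]
        result = optimize_model(spectra, Y.to_numpy(), specs, 3)
        assert len(result.leaderboard) == 6

    def test_no_candidates_rejected(self, coarse_grid):
        spectra, Y = two_species_data(grid=coarse_grid)
        with pytest.raises(ContractError):
            optimize_model(spectra, Y.to_numpy(), [], 3)


class TestExternalValidation:
    def test_validating_on_calibration_set_reproduces_rmsee(self, coarse_grid):
        spectra, Y = two_species_data(grid=coarse_grid)
        X, _, _ = apply_pipeline(spectra, PreprocessSpec())
        model = fit_pls(X, Y.to_numpy(), 3, species=list(Y.columns))
        cal = metrics_table(Y.to_numpy(), predict(model, X), model.species,
                            "calibration")
        report = external_validation(model, X, Y.to_numpy())
        for sp in model.species:
            assert report.metrics[sp].rmse == pytest.approx(cal[sp].rmse, abs=1e-12)
            assert report.metrics[sp].context == "prediction"

    def test_constant_shift_shows_as_bias_and_intercept(self, rng):
        X = rng.normal(size=(10, 4))
        Y = rng.uniform(10, 90, size=(10, 1))
        model = fit_pls(X, Y, 3, species=("maize",))
        X_test = rng.normal(size=(8, 4))
        truth = predict(model, X_test) - 5.0  # predictions are truth + 5
        report = external_validation(model, X_test, truth)
        m = report.metrics["maize"]
        slope, intercept = report.lines["maize"]
        assert m.bias == pytest.approx(5.0, abs=1e-8)
        assert slope == pytest.approx(1.0, abs=1e-8)
        assert intercept == pytest.approx(5.0, abs=1e-6)

    def test_metrics_match_from_scratch_recomputation(self, coarse_grid):
        """Oracle: recompute every reported metric from the stored
        predictions with independent formulas."""
        design = design_2species(5.0)
        from rootspec.simulate import simulate_mixture_set

        cal, Y = simulate_mixture_set(design, 1, noise=NoiseModel.dried(8),
                                      grid=coarse_grid)
        test_design = design_2species(20.0)
        test, Yt = simulate_mixture_set(test_design, 1, noise=NoiseModel.dried(99),
                                        grid=coarse_grid)
        spec = PreprocessSpec()
        X, _, _ = apply_pipeline(cal, spec)
        Xt, _, _ = apply_pipeline(test, spec)
        model = fit_pls(X, Y.to_numpy(), 3, species=list(Y.columns))
        report = external_validation(model, Xt, Yt.to_numpy())
        preds = report.predictions
        for j, sp in enumerate(model.species):
            y, yhat = Yt.to_numpy()[:, j], preds[:, j]
            err = yhat - y
            m = report.metrics[sp]
            assert m.rmse == pytest.approx(np.sqrt(np.mean(err**2)), abs=1e-12)
            assert m.bias == pytest.approx(np.mean(err), abs=1e-12)
            assert m.rpd == pytest.approx(np.std(y, ddof=1) / m.rmse, abs=1e-9)
            assert m.r2 == pytest.approx(
                1 - np.sum(err**2) / np.sum((y - y.mean()) ** 2), abs=1e-12
            )
            assert m.r == pytest.approx(np.corrcoef(y, yhat)[0, 1], abs=1e-12)

    def test_small_test_set_flagged_unstable(self, rng):
        X = rng.normal(size=(8, 3))
        Y = rng.uniform(0, 100, size=(8, 1))
        model = fit_pls(X, Y, 2, species=("maize",))
        report = external_validation(model, X[:2], Y[:2])
        assert report.metrics["maize"].unstable
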