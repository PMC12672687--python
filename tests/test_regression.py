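import numpy as np
import pytest

from mvcalib import (
    ConcentrationMatrix,
    SpectraMatrix,
    build_wavelength_grid,
    fit_pcr,
    fit_pls,
    predict,
    predict_via_scores,
    simulate_mixtures,
    unit_spectra,
)
from mvcalib.regression import load_model, pls_nipals, save_model
from mvcalib.validate import rmse


def ols_oracle(Xc, Yc, Xc_new):
    """Normal-equations least squares restricted to the X column space."""
    B = np.linalg.pinv(Xc) @ Yc
    return Xc_new @ B


def random_instance(rng, n=12, p=8, m=2, noise=0.05):
    g = build_wavelength_grid(0.0, float(p - 1), 1.0)
    ids = tuple(f"s{i}" for i in range(n))
    Xv = rng.normal(1.0, 0.5, (n, p))
    Yv = rng.uniform(1.0, 5.0, (n, m)) + noise * rng.normal(size=(n, m))
    return SpectraMatrix(ids, g, Xv), ConcentrationMatrix(ids, tuple(f"a{j}" for j in range(m)), Yv)


class TestExactRecovery:
    def test_pcr_rmsec_noiseless(self, noiseless_run):
        Xcal, Ycal, _, _ = noiseless_run
        model = fit_pcr(Xcal, Ycal, 4)
        fitted = predict(model, Xcal)
        for k in range(4):
            assert rmse(fitted.values[:, k], Ycal.values[:, k]) < 1e-8

    def test_pls_rmsec_noiseless_joint(self, noiseless_run):
        Xcal, Ycal, _, _ = noiseless_run
        model = fit_pls(Xcal, Ycal, 4)
        fitted = predict(model, Xcal)
        for k in range(4):
            assert rmse(fitted.values[:, k], Ycal.values[:, k]) < 1e-8

    def test_noiseless_validation_recoveries_exact(self, noiseless_run):
        Xcal, Ycal, Xval, Yval = noiseless_run
        model = fit_pls(Xcal, Ycal, 4)
        Yhat = predict(model, Xval)
        rec = 100.0 * Yhat.values / Yval.values
        np.testing.assert_allclose(rec, 100.0, atol=1e-6)

    def test_rank_one_system_recovered(self, grid, pure_models):
        ids = tuple(f"s{i}" for i in range(5))
        conc = ConcentrationMatrix(ids, ("SAF",), np.array([[3.0], [8.0], [13.0], [18.0], [23.0]]))
        X = simulate_mixtures(pure_models[:1], conc, grid, noise=None)
        model = fit_pcr(X, conc, 1)
        np.testing.assert_allclose(predict(model, X).values, conc.values, atol=1e-8)


class TestOracleEquivalence:
    def test_pcr_at_full_rank_equals_least_squares(self, rng):
        for _ in range(5):
            X, Y = random_instance(rng, p=30)  # wide X: rank = n_samples - 1
            model = fit_pcr(X, Y, X.n_samples - 1)
            Xc = X.absorbance - X.absorbance.mean(axis=0)
            expected = ols_oracle(Xc, Y.values - Y.values.mean(axis=0), Xc) + Y.values.mean(axis=0)
            np.testing.assert_allclose(predict(model, X).values, expected, atol=1e-8)

    def test_pls_saturated_equals_least_squares_single_response(self, rng):
        for _ in range(5):
            X, Y = random_instance(rng, m=1)
            model = fit_pls(X, Y, min(X.n_samples - 1, X.grid.n_points))
            Xc = X.absorbance - X.absorbance.mean(axis=0)
            expected = ols_oracle(Xc, Y.values - Y.values.mean(axis=0), Xc) + Y.values.mean(axis=0)
            np.testing.assert_allclose(predict(model, X).values, expected, atol=1e-8)

    def test_pcr_and_pls_agree_at_saturation(self, rng):
        for _ in range(5):
            X, Y = random_instance(rng, n=10, p=6, m=2)
            k = min(X.n_samples - 1, X.grid.n_points)
            p1 = predict(fit_pcr(X, Y, k), X).values
            p2 = predict(fit_pls(X, Y, k), X).values
            np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_first_pls_weight_is_covariance_direction(self, rng):
        X, Y = random_instance(rng, m=1)
        Xc = X.absorbance - X.absorbance.mean(axis=0)
        yc = Y.values - Y.values.mean(axis=0)
        W, _, _, _ = pls_nipals(Xc, yc, 1)
        cov = (Xc.T @ yc)[:, 0]
        cos = abs(cov @ W[:, 0]) / np.linalg.norm(cov)
        assert cos > 1 - 1e-10


class TestModelStructure:
    def test_pls_weights_unit_norm_scores_orthogonal(self, noisy_run):
        Xcal, Ycal, _, _ = noisy_run
        model = fit_pls(Xcal, Ycal, 5)
        norms = np.linalg.norm(model.weights, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_scores_path_equals_coefficients_path(self, noisy_run):
        Xcal, Ycal, Xval, _ = noisy_run
        for fitter in (fit_pcr, fit_pls):
            model = fitter(Xcal, Ycal, 5)
            a = predict(model, Xval).values
            b = predict_via_scores(model, Xval).values
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_sign_convention_deterministic(self, noisy_run):
        Xcal, Ycal, _, _ = noisy_run
        m1 = fit_pls(Xcal, Ycal, 3)
        m2 = fit_pls(Xcal, Ycal, 3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert all(m1.weights[np.argmax(np.abs(m1.weights[:, a])), a] > 0 for a in range(3))

    def test_per_analyte_mode_matches_joint_for_one_response(self, rng):
        X, Y = random_instance(rng, m=1)
        pj = predict(fit_pls(X, Y, 3, mode="joint"), X).values
        pa = predict(fit_pls(X, Y, 3, mode="per_analyte"), X).values
        np.testing.assert_allclose(pj, pa, atol=1e-10)


class TestPredictionContracts:
    def test_masked_model_ignores_other_columns(self, noisy_run, rng):
        Xcal, Ycal, Xval, _ = noisy_run
        mask = np.zeros(Xcal.grid.n_points, dtype=bool)
        mask[200:500] = True
        model = fit_pls(Xcal, Ycal, 3, wavelength_mask=mask)
        before = predict(model, Xval).values
        perturbed = Xval.absorbance.copy()
        perturbed[:, ~mask] += rng.normal(0, 10.0, size=perturbed[:, ~mask].shape)
        Xp = SpectraMatrix(Xval.sample_ids, Xval.grid, perturbed)
        np.testing.assert_array_equal(predict(model, Xp).values, before)

    def test_grid_mismatch_rejected(self, noisy_run):
        Xcal, Ycal, _, _ = noisy_run
        model = fit_pls(Xcal, Ycal, 3)
        other = build_wavelength_grid(220.0, 400.0, 0.5)
        Xo = SpectraMatrix(("s1",), other, np.zeros((1, other.n_points)))
        with pytest.raises(ValueError, match="grid mismatch"):
            predict(model, Xo)

    def test_y_scaling_equivariance(self, noiseless_run):
        Xcal, Ycal, Xval, _ = noiseless_run
        scaled = ConcentrationMatrix(Ycal.sample_ids, Ycal.analyte_names, 3.0 * Ycal.values)
        p1 = predict(fit_pls(Xcal, Ycal, 4), Xval).values
        p2 = predict(fit_pls(Xcal, scaled, 4), Xval).values
        np.testing.assert_allclose(p2, 3.0 * p1, rtol=1e-8)

    def test_wavelength_permutation_invariance(self, rng):
        X, Y = random_instance(rng, n=14, p=10, m=2)
        perm = rng.permutation(X.grid.n_points)
        Xp = SpectraMatrix(X.sample_ids, X.grid, X.absorbance[:, perm])
        p1 = predict(fit_pls(X, Y, 4), X).values
        p2 = predict(fit_pls(Xp, Y, 4), Xp).values
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_n_lv_bound_enforced(self, rng):
        X, Y = random_instance(rng, n=6, p=20)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(X, Y, 6)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pcr(X, Y, 0)


def test_model_bundle_round_trip(tmp_path, noisy_run):
    Xcal, Ycal, Xval, _ = noisy_run
    model = fit_pls(Xcal, Ycal, 4)
    save_model(model, tmp_path / "m")
    loaded = load_model(tmp_path / "m")
    np.testing.assert_allclose(
        predict(loaded, Xval).values, predict(model, Xval).values, rtol=1e-10
    )
    assert loaded.algorithm == "PLS" and loaded.n_lv == 4


def test_pls_matches_sklearn_reference(rng):
    """Independent oracle: scikit-learn's PLSRegression (its own NIPALS
    implementation) must give the same predictions for the same LV count.

    Single-response PLS has a closed-form weight per component, so the two
    implementations agree to machine precision; for multiple responses
    scikit-learn's inner iteration uses a different (looser) stopping rule,
    so agreement is only to the level its convergence leaves undetermined.
    """
    from sklearn.cross_decomposition import PLSRegression

    X1, Y1 = random_instance(rng, n=15, p=12, m=1)
    for n_lv in (1, 3, 5):
        ours = predict(fit_pls(X1, Y1, n_lv), X1).values
        ref = PLSRegression(n_components=n_lv, scale=False).fit(
            X1.absorbance, Y1.values
        ).predict(X1.absorbance)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    Xm, Ym = random_instance(rng, n=15, p=12, m=3)
    for n_lv in (1, 3, 5):
        ours = predict(fit_pls(Xm, Ym, n_lv), Xm).values
        ref = PLSRegression(n_components=n_lv, scale=False, tol=1e-12).fit(
            Xm.absorbance, Ym.values
        ).predict(Xm.absorbance)
        np.testing.assert_allclose(ours, ref, atol=1e-4)
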