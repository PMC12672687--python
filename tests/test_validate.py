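import numpy as np
import pytest
from hypothesis import given, strategies as st

from mvcalib import (
    ConcentrationMatrix,
    SpectraMatrix,
    build_wavelength_grid,
    compare_methods,
    cross_validate,
    fit_pls,
    linear_diagnostics,
    lod_loq,
    make_folds,
    recovery_stats,
    rmse,
    select_lv,
    standard_addition_recovery,
    validation_report,
)
from mvcalib.validate import CvScheme, oof_predictions
from mvcalib import _fast


class TestFolds:
    def test_leave_one_out_counts(self):
        folds = make_folds(CvScheme("leave_one_out"), 17)
        assert len(folds) == 17
        assert all(test.size == 1 for _, test in folds)

    @pytest.mark.parametrize(
        "kind", ["leave_one_out", "venetian_blinds", "contiguous_blocks", "random_subsets"]
    )
    def test_every_sample_held_out_exactly_once(self, kind):
        folds = make_folds(CvScheme(kind, n_splits=4, seed=3), 14)
        held = np.concatenate([test for _, test in folds])
        assert sorted(held) == list(range(14))
        for train, test in folds:
            assert not set(train) & set(test)
            assert len(set(train) | set(test)) == 14

    def test_venetian_blinds_striping(self):
        folds = make_folds(CvScheme("venetian_blinds", n_splits=3), 9)
        np.testing.assert_array_equal(folds[0][1], [0, 3, 6])
        np.testing.assert_array_equal(folds[1][1], [1, 4, 7])

    def test_contiguous_blocks_are_runs(self):
        folds = make_folds(CvScheme("contiguous_blocks", n_splits=3), 9)
        np.testing.assert_array_equal(folds[0][1], [0, 1, 2])
        np.testing.assert_array_equal(folds[2][1], [6, 7, 8])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CvScheme("bootstrap")


class TestCrossValidate:
    def test_exact_system_reaches_machine_zero_at_four_lvs(self, noiseless_run):
        Xcal, Ycal, _, _ = noiseless_run
        res = cross_validate(Xcal, Ycal, CvScheme("leave_one_out"), 4)
        assert res.pooled[3] < 1e-8

    def test_loo_equals_handrolled_loop_on_toy_system(self, rng):
        # 6-sample toy: refit per left-out sample with an explicit loop
        g = build_wavelength_grid(0.0, 4.0, 1.0)
        ids = tuple(f"s{i}" for i in range(6))
        Xv = rng.uniform(0, 1, (6, 5))
        Yv = rng.uniform(1, 4, (6, 2))
        X, Y = SpectraMatrix(ids, g, Xv), ConcentrationMatrix(ids, ("a", "b"), Yv)
        res = cross_validate(X, Y, CvScheme("leave_one_out"), 2)
        from mvcalib.regression import pls_nested_predictions, pls_nipals

        errs = np.empty((2, 6, 2))
        for i in range(6):
            tr = [j for j in range(6) if j != i]
            xm, ym = Xv[tr].mean(axis=0), Yv[tr].mean(axis=0)
            W, P, Q, _ = pls_nipals(Xv[tr] - xm, Yv[tr] - ym, 2)
            pred = pls_nested_predictions(W, P, Q, (Xv[i] - xm)[None]) + ym
            errs[:, i] = pred[:, 0] - Yv[i]
        expected = np.sqrt((errs**2).mean(axis=(1, 2)))
        np.testing.assert_allclose(res.pooled, expected, atol=1e-10)

    def test_fast_and_reference_paths_agree(self, noisy_run):
        Xcal, Ycal, _, _ = noisy_run
        if not _fast.HAVE_NUMBA:
            pytest.skip("compiled kernel unavailable")
        Xm = Xcal.absorbance[:, 400:700]
        folds = make_folds(CvScheme("leave_one_out"), 17)
        fast_p, fast_b = oof_predictions(Xm, Ycal.values, folds, 4)
        _fast.HAVE_NUMBA = False
        try:
            ref_p, ref_b = oof_predictions(Xm, Ycal.values, folds, 4)
        finally:
            _fast.HAVE_NUMBA = True
        np.testing.assert_allclose(fast_p, ref_p, atol=1e-10)
        np.testing.assert_allclose(fast_b, ref_b, atol=1e-12)

    def test_small_training_fold_rejected(self, rng):
        g = build_wavelength_grid(0.0, 3.0, 1.0)
        ids = ("a", "b")
        X = SpectraMatrix(ids, g, rng.uniform(0, 1, (2, 4)))
        Y = ConcentrationMatrix(ids, ("c",), rng.uniform(1, 2, (2, 1)))
        with pytest.raises(ValueError, match="fewer than 2"):
            cross_validate(X, Y, CvScheme("leave_one_out"), 1)


class TestSelectLv:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([5, 3, 1, 1.0000001], 3),
            ([2, 2], 1),
            ([8, 7, 6, 5, 4, 3, 2, 1], 8),
        ],
    )
    def test_argmin_with_tie_rule(self, curve, expected):
        assert select_lv(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_lv([])


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_arithmetic_example(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_elementwise_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            a, b = rng.normal(size=n), rng.normal(size=n)
            acc = 0.0
            for x, y in zip(a, b):
                acc += (x - y) ** 2
            assert rmse(a, b) == pytest.approx(np.sqrt(acc / n), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])


class TestRecoveryStats:
    def test_perfect_recovery(self):
        mean, sd, rsd = recovery_stats([2.0, 3.0], [2.0, 3.0])
        assert (mean, sd, rsd) == (100.0, 0.0, 0.0)

    def test_mean_of_three_spike_recoveries_first_method(self):
        # standard-addition recoveries averaged to the reported mean
        recs = np.array([98.67, 100.61, 102.05])
        mean, _, _ = recovery_stats(recs / 100.0, np.ones(3))
        assert round(mean, 2) == 100.44

    def test_mean_of_three_spike_recoveries_interval_method(self):
        recs = np.array([101.99, 102.05, 99.13])
        mean, _, _ = recovery_stats(recs / 100.0, np.ones(3))
        assert round(mean, 2) == 101.06

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            recovery_stats([1.0], [0.0])


class TestLinearDiagnostics:
    def test_identity_line(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert linear_diagnostics(t, t) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line(self):
        t = np.array([1.0, 2.0, 3.0])
        assert linear_diagnostics(2 * t + 1, t) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_closed_form_oracle(self, rng):
        t = rng.uniform(0, 10, 20)
        p = 1.3 * t + rng.normal(0, 0.5, 20)
        slope, intercept, r = linear_diagnostics(p, t)
        sxy = np.sum((t - t.mean()) * (p - p.mean()))
        sxx = np.sum((t - t.mean()) ** 2)
        syy = np.sum((p - p.mean()) ** 2)
        assert slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert intercept == pytest.approx(p.mean() - sxy / sxx * t.mean(), abs=1e-10)
        assert r == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_diagnostics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestLodLoq:
    def test_arithmetic_example(self):
        lod, loq = lod_loq(0.3, 1.5)
        assert lod == pytest.approx(0.66)
        assert loq == pytest.approx(2.0)

    def test_zero_sd_gives_zero_limits(self):
        assert lod_loq(0.0, 2.0) == (0.0, 0.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            lod_loq(0.1, 0.0)

    @given(st.floats(1e-6, 10.0), st.floats(0.1, 5.0))
    def test_ratio_is_ten_thirds_point_three_exactly(self, sd, slope):
        lod, loq = lod_loq(sd, slope)
        assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-15)


class TestStandardAddition:
    def test_full_recovery(self):
        rec = standard_addition_recovery(6.0, [3.0], [9.0])
        assert rec[0] == pytest.approx(100.0)

    def test_inverse_relation_reproduces_reported_recovery(self):
        # totals constructed from a printed per-spike recovery round-trip to it
        base, added, target = 5.913, 3.0, 98.67
        total = base + added * target / 100.0
        rec = standard_addition_recovery(base, [added], [total])
        assert rec[0] == pytest.approx(target, abs=1e-10)

    def test_zero_added_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            standard_addition_recovery(6.0, [0.0], [6.0])


class TestCompareMethods:
    def test_identical_samples_give_zero_t(self):
        out = compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["F"] == pytest.approx(1.0)

    def test_equal_variances_give_unit_f(self):
        out = compare_methods([1.0, 2.0], [5.0, 6.0])
        assert out["F"] == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        for _ in range(100):
            na, nb = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            a, b = rng.normal(10, 1, na), rng.normal(10.5, 1.5, nb)
            out = compare_methods(a, b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
            t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
            assert out["t"] == pytest.approx(t, abs=1e-10)
            assert out["F"] == pytest.approx(max(va, vb) / min(va, vb), abs=1e-10)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_methods([1.0, 1.0], [2.0, 2.0])


class TestValidationReport:
    def test_report_statistics_on_noisy_validation(self, noisy_run):
        Xcal, Ycal, Xval, Yval = noisy_run
        model = fit_pls(Xcal, Ycal, 4)
        rep = validation_report(model, Xval, Yval)
        t = rep.table
        assert list(t.index) == ["SAF", "HBD", "HYD", "OXD"]
        assert (t["rmsep"] >= 0).all()
        np.testing.assert_allclose(t["loq"] / t["lod"], 10.0 / 3.3, rtol=1e-15)
        np.testing.assert_allclose(
            t["rsd_pct"], 100.0 * t["sd_recovery"] / t["mean_recovery_pct"], rtol=1e-12
        )
        assert (t["r"] > 0.999).all()  # near-exact synthetic system

    def test_rounded_rendering_precision(self, noisy_run):
        Xcal, Ycal, Xval, Yval = noisy_run
        rep = validation_report(fit_pls(Xcal, Ycal, 4), Xval, Yval)
        r = rep.rounded()
        assert (r["mean_recovery_pct"] * 100 % 1 == 0).all()  # 2 dp
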