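"""Cross-validation engines and assay validation statistics.

Covers the numerical side of method validation for a multivariate
spectrophotometric assay: RMSEC/RMSECV/RMSEP, latent-variable selection from
RMSECV curves, recovery statistics, predicted-vs-true regression diagnostics,
LOD/LOQ from residual scatter and slope, standard-addition recovery, and the
two-sample t and variance-ratio F comparisons used to benchmark a new method
against a reference one.

Cross-validation always refits preprocessing on each training fold, so no
information from held-out samples leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _fast
from .preprocess import apply_preprocess, fit_preprocess, invert_center
from .regression import (
    CalibrationModel,
    pcr_nested_predictions,
    pcr_svd,
    pls_nested_predictions,
    pls_nipals,
    predict,
)
from .spectra_io import ConcentrationMatrix, SpectraMatrix, align_blocks

__all__ = [
    "CvScheme",
    "CvResult",
    "ValidationReport",
    "make_folds",
    "cross_validate",
    "select_lv",
    "rmse",
    "recovery_stats",
    "linear_diagnostics",
    "lod_loq",
    "standard_addition_recovery",
    "compare_methods",
    "validation_report",
]

CV_KINDS = ("leave_one_out", "venetian_blinds", "contiguous_blocks", "random_subsets")


@dataclass(frozen=True)
class CvScheme:
    """A cross-validation fold layout.

    ``venetian_blinds`` assigns sample i to fold ``i mod n_splits`` in input
    order; ``contiguous_blocks`` cuts the ordered samples into ``n_splits``
    runs; ``random_subsets`` shuffles with ``seed`` first.  ``n_splits`` and
    ``seed`` are ignored where not applicable.
    """

    kind: str = "leave_one_out"
    n_splits: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}; choose from {CV_KINDS}")
        if self.kind != "leave_one_out" and self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


def make_folds(scheme: CvScheme, n_samples: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialise (train_indices, test_indices) pairs; folds are disjoint and
    every sample is held out exactly once."""
    idx = np.arange(n_samples)
    if scheme.kind == "leave_one_out":
        test_sets = [idx[i : i + 1] for i in range(n_samples)]
    elif scheme.kind == "venetian_blinds":
        test_sets = [idx[j :: scheme.n_splits] for j in range(scheme.n_splits)]
    elif scheme.kind == "contiguous_blocks":
        test_sets = [b for b in np.array_split(idx, scheme.n_splits) if b.size]
    else:  # random_subsets
        perm = np.random.default_rng(scheme.seed).permutation(n_samples)
        test_sets = [np.sort(b) for b in np.array_split(perm, scheme.n_splits) if b.size]
    folds = []
    for test in test_sets:
        mask = np.ones(n_samples, dtype=bool)
        mask[test] = False
        folds.append((idx[mask], test))
    return folds


# ---------------------------------------------------------------------------
# cross-validation core (array level; shared with the siPLS search)
# ---------------------------------------------------------------------------

def oof_predictions(
    X: np.ndarray,
    Y: np.ndarray,
    folds,
    max_lv: int,
    algorithm: str = "pls",
    preprocess: str = "mean_center",
    mode: str = "joint",
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions at every LV count 1..max_lv.

    Returns ``(preds, baseline)`` where ``preds`` is (max_lv, n, m) in
    original units and ``baseline`` (n, m) is the 0-LV intercept-only model
    (each held-out sample predicted by its training fold's mean Y).
    """
    n, m = Y.shape
    for train, test in folds:
        if train.size < 2:
            raise ValueError("cross-validation fold with fewer than 2 training samples")
        bound = min(train.size - 1, X.shape[1])
        if max_lv > bound:
            raise ValueError(
                f"max_lv={max_lv} exceeds the fold bound min(n_train-1, n_columns)={bound}"
            )
    if (
        _fast.HAVE_NUMBA
        and algorithm == "pls"
        and mode == "joint"
        and preprocess == "mean_center"
    ):
        # compiled kernel; same NIPALS recursion, checked against the numpy
        # path in the test suite
        from .regression import NIPALS_MAX_ITER, NIPALS_TOL

        order, bounds = _fast.folds_to_arrays(folds)
        return _fast.pls_oof_mean_center(
            np.ascontiguousarray(X, dtype=float),
            np.ascontiguousarray(Y, dtype=float),
            order,
            bounds,
            max_lv,
            NIPALS_TOL,
            NIPALS_MAX_ITER,
        )
    preds = np.empty((max_lv, n, m))
    baseline = np.empty((n, m))
    for train, test in folds:
        xp = fit_preprocess(X[train], preprocess)
        yp = fit_preprocess(Y[train], preprocess)
        Xc, Yc = apply_preprocess(xp, X[train]), apply_preprocess(yp, Y[train])
        Xt = apply_preprocess(xp, X[test])
        if algorithm == "pls" and mode == "joint":
            W, P, Q, _ = pls_nipals(Xc, Yc, max_lv)
            block = pls_nested_predictions(W, P, Q, Xt)
        elif algorithm == "pls":
            block = np.empty((max_lv, test.size, m))
            for k in range(m):
                W, P, Q, _ = pls_nipals(Xc, Yc[:, k : k + 1], max_lv)
                block[:, :, k] = pls_nested_predictions(W, P, Q, Xt)[:, :, 0]
        elif algorithm == "pcr":
            V, C, _ = pcr_svd(Xc, Yc, max_lv)
            block = pcr_nested_predictions(V, C, Xt)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        for k in range(max_lv):
            preds[k, test] = invert_center(yp, block[k])
        baseline[test] = Y[train].mean(axis=0)
    return preds, baseline


def _rmse_curves(preds: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sq = (preds - Y[None]) ** 2  # (max_lv, n, m)
    per_analyte = np.sqrt(sq.mean(axis=1))  # (max_lv, m)
    pooled = np.sqrt(sq.mean(axis=(1, 2)))  # (max_lv,)
    return per_analyte, pooled


@dataclass(frozen=True)
class CvResult:
    """RMSECV curves: one value per LV count (1-based) per analyte, plus the
    pooled curve used for ranking/selection and the 0-LV baseline."""

    lv_counts: tuple[int, ...]
    per_analyte: np.ndarray = field(repr=False)  # (max_lv, m)
    pooled: np.ndarray = field(repr=False)  # (max_lv,)
    baseline_per_analyte: np.ndarray = field(repr=False)
    baseline_pooled: float = 0.0
    analyte_names: tuple[str, ...] = ()


def cross_validate(
    X: SpectraMatrix,
    Y: ConcentrationMatrix,
    scheme: CvScheme,
    max_lv: int,
    algorithm: str = "pls",
    preprocess: str = "mean_center",
    mode: str = "joint",
    wavelength_mask=None,
) -> CvResult:
    """RMSECV of a PCR/PLS model at every LV count 1..max_lv.

    For each fold the preprocessing and the model are fitted on the training
    fold only; held-out predictions are accumulated and
    ``RMSECV_k = sqrt(sum((yhat - y)^2) / n)`` over all held-out samples.
    """
    X, Y = align_blocks(X, Y)
    Xm = X.absorbance if wavelength_mask is None else X.absorbance[:, wavelength_mask]
    folds = make_folds(scheme, X.n_samples)
    preds, baseline = oof_predictions(
        Xm, Y.values, folds, max_lv, algorithm=algorithm, preprocess=preprocess, mode=mode
    )
    per_analyte, pooled = _rmse_curves(preds, Y.values)
    base_pa, base_pooled = _rmse_curves(baseline[None], Y.values)
    return CvResult(
        lv_counts=tuple(range(1, max_lv + 1)),
        per_analyte=per_analyte,
        pooled=pooled,
        baseline_per_analyte=base_pa[0],
        baseline_pooled=float(base_pooled[0]),
        analyte_names=Y.analyte_names,
    )


def select_lv(rmsecv_curve) -> int:
    """LV count at the global RMSECV minimum; ties go to the smaller count.

    The curve's first entry is taken to be the 1-LV model.
    """
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    return int(np.argmin(curve)) + 1


# ---------------------------------------------------------------------------
# scalar validation statistics
# ---------------------------------------------------------------------------

def rmse(predicted, true) -> float:
    """Root mean square error sqrt(sum((yhat - y)^2)/n).

    The same formula serves as RMSEC, RMSECV or RMSEP depending on whether
    the predictions are in-fit, cross-validated or external.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.size != true.size:
        raise ValueError(f"length mismatch: {predicted.size} vs {true.size}")
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


def recovery_stats(predicted, true) -> tuple[float, float, float]:
    """Mean recovery %, its sample SD (n-1) and RSD % = 100*SD/mean.

    Per-sample recovery is 100 * predicted / true; all true values must be
    positive.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if np.any(true <= 0):
        raise ValueError("recovery undefined for non-positive true concentrations")
    rec = 100.0 * predicted / true
    mean = float(rec.mean())
    sd = float(rec.std(ddof=1)) if rec.size > 1 else 0.0
    return mean, sd, 100.0 * sd / mean


def linear_diagnostics(predicted, true) -> tuple[float, float, float]:
    """(slope, intercept, r) of the OLS line predicted = slope*true + intercept."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if predicted.size < 3:
        raise ValueError("need at least 3 points for regression diagnostics")
    if np.ptp(true) == 0:
        raise ValueError("true values have zero variance")
    res = stats.linregress(true, predicted)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def lod_loq(residual_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits: LOD = 3.3*SD/S, LOQ = 10*SD/S.

    SD is the standard deviation of the predicted-vs-true regression
    residuals and S the regression slope; LOQ is derived from LOD so the
    LOQ/LOD ratio is 10/3.3 to machine precision.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if residual_sd < 0:
        raise ValueError("residual SD must be >= 0")
    lod = 3.3 * residual_sd / abs(slope)
    return lod, lod * (10.0 / 3.3)


def standard_addition_recovery(base_found, added_levels, totals_found) -> np.ndarray:
    """Recovery % of the pure added standard at each spiking level.

    ``recovery_i = 100 * (total_found_i - base_found) / added_i`` where
    ``base_found`` is the assayed unspiked amount.
    """
    added = np.asarray(added_levels, dtype=float).ravel()
    totals = np.asarray(totals_found, dtype=float).ravel()
    if added.size != totals.size:
        raise ValueError("added_levels and totals_found must have equal length")
    if np.any(added <= 0):
        raise ValueError("added amounts must be positive")
    return 100.0 * (totals - float(base_found)) / added


def compare_methods(results_a, results_b) -> dict[str, float]:
    """Student's t (equal-variance) and variance-ratio F comparison.

    F puts the larger variance in the numerator; both p-values are
    two-sided.  Returns keys ``t, t_p, F, F_p, df_t, df_F_num, df_F_den``.
    """
    a = np.asarray(results_a, dtype=float).ravel()
    b = np.asarray(results_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per method")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("variance ratio undefined: both samples have zero variance")
    t_res = stats.ttest_ind(a, b, equal_var=True)
    if va >= vb:
        F, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p_one = stats.f.sf(F, dfn, dfd)
    return {
        "t": float(t_res.statistic),
        "t_p": float(t_res.pvalue),
        "df_t": float(a.size + b.size - 2),
        "F": float(F),
        "F_p": float(min(1.0, 2.0 * p_one)),
        "df_F_num": float(dfn),
        "df_F_den": float(dfd),
    }


# ---------------------------------------------------------------------------
# external-validation report
# ---------------------------------------------------------------------------

REPORT_STATISTICS = (
    "rmsep",
    "mean_recovery_pct",
    "sd_recovery",
    "rsd_pct",
    "slope",
    "intercept",
    "r",
    "lod",
    "loq",
)


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte external-validation statistics (analytes x statistics)."""

    table: pd.DataFrame = field(repr=False)

    def rounded(self) -> pd.DataFrame:
        """Report-precision rendering: recoveries to 2 dp, regression
        parameters to 4 dp, errors and limits to 3 dp."""
        out = self.table.copy()
        for col in ("mean_recovery_pct", "sd_recovery", "rsd_pct"):
            out[col] = out[col].round(2)
        for col in ("slope", "intercept", "r"):
            out[col] = out[col].round(4)
        for col in ("rmsep", "lod", "loq"):
            out[col] = out[col].round(3)
        return out


def validation_report(
    model: CalibrationModel, X_val: SpectraMatrix, Y_val: ConcentrationMatrix
) -> ValidationReport:
    """Predict the external validation set and assemble the statistics table.

    LOD/LOQ use the SD of the predicted-vs-true regression residuals (n-2
    degrees of freedom) and the slope of that regression.
    """
    X_val, Y_val = align_blocks(X_val, Y_val)
    Y_hat = predict(model, X_val)
    rows = {}
    for k, name in enumerate(Y_val.analyte_names):
        y, yhat = Y_val.values[:, k], Y_hat.values[:, k]
        slope, intercept, r = linear_diagnostics(yhat, y)
        residuals = yhat - (slope * y + intercept)
        resid_sd = float(np.sqrt((residuals**2).sum() / (y.size - 2)))
        lod, loq = lod_loq(resid_sd, slope)
        mean_rec, sd_rec, rsd = recovery_stats(yhat, y)
        rows[name] = {
            "rmsep": rmse(yhat, y),
            "mean_recovery_pct": mean_rec,
            "sd_recovery": sd_rec,
            "rsd_pct": rsd,
            "slope": slope,
            "intercept": intercept,
            "r": r,
            "lod": lod,
            "loq": loq,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(REPORT_STATISTICS)]
    table.index.name = "analyte"
    return ValidationReport(table)
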