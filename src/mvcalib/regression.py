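"""Latent-variable regression: principal component regression and PLS.

Both algorithms regress a concentration block Y (samples x analytes, ug/mL)
on an absorbance block X (samples x wavelengths, AU) through a small number
of latent variables:

* **PCR** — PCA of the (preprocessed) X block by singular-value
  decomposition, components ordered by decreasing explained variance,
  followed by least squares of Y on the scores.  The decomposition ignores Y.
* **PLS** — iterative NIPALS with X-block deflation; each weight vector
  maximises the covariance between X scores and Y, so the components are
  tailored to prediction.  Joint (all analytes at once, PLS2) and
  per-analyte (PLS1) modes are provided.

Sign convention: every weight/loading vector is flipped so its element of
largest magnitude is positive, making fitted models reproducible across runs.

At saturation (as many components as the rank of centred X) both methods
coincide with ordinary least squares on the X column space — the basis of the
oracle cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessParams, apply_preprocess, fit_preprocess, invert_center
from .spectra_io import ConcentrationMatrix, SpectraMatrix, WavelengthGrid, align_blocks

__all__ = [
    "CalibrationModel",
    "fit_pcr",
    "fit_pls",
    "predict",
    "predict_via_scores",
    "save_model",
    "load_model",
]

#: relative convergence tolerance for a NIPALS weight vector
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted PCR or PLS calibration.

    ``coefficients`` (masked wavelengths x analytes) map preprocessed
    absorbances to preprocessed concentrations; :func:`predict` handles the
    preprocessing round trip so its output is in ug/mL.
    """

    algorithm: str  # "PCR" | "PLS"
    n_lv: int
    x_preprocess: PreprocessParams
    y_preprocess: PreprocessParams
    grid: WavelengthGrid
    wavelength_mask: np.ndarray = field(repr=False)  # boolean over grid columns
    analyte_names: tuple[str, ...] = ()
    x_loadings: np.ndarray = field(default=None, repr=False)  # p_masked x A
    x_scores: np.ndarray = field(default=None, repr=False)  # n x A
    y_loadings: np.ndarray = field(default=None, repr=False)  # m x A
    weights: np.ndarray = field(default=None, repr=False)  # p_masked x A, PLS only
    coefficients: np.ndarray = field(default=None, repr=False)  # p_masked x m
    mode: str = "joint"


# ---------------------------------------------------------------------------
# array-level cores (shared by model fitting and the cross-validation engine)
# ---------------------------------------------------------------------------

def _flip_signs(w: np.ndarray) -> float:
    """Return +-1 so that the largest-|.| element of w becomes positive."""
    i = int(np.argmax(np.abs(w)))
    return 1.0 if w[i] >= 0 else -1.0


def pls_nipals(
    Xc: np.ndarray,
    Yc: np.ndarray,
    n_lv: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS on preprocessed arrays; returns (W, P, Q, T).

    W (p x A) X-weights (unit norm), P (p x A) X-loadings, Q (m x A)
    Y-loadings, T (n x A) scores.  X is deflated after each component; for a
    single response the weight update has an immediate fixed point, for
    multiple responses the iteration is warm-started at the dominant singular
    direction of X'Y and refined until the weight vector changes by less than
    ``tol`` (relative) or ``max_iter`` is hit (-> ConvergenceError naming the
    component).
    """
    X = np.array(Xc, dtype=float)
    Y = np.array(Yc, dtype=float)
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        S = X.T @ Y  # p x m covariance block
        if m == 1:
            w = S[:, 0]
            nw = np.linalg.norm(w)
            if nw <= 0:
                raise ConvergenceError(
                    f"PLS component {a + 1}: X residual carries no covariance with Y "
                    "(constant or rank-deficient X)"
                )
            w = w / nw
        else:
            # dominant right-singular direction of S from the m x m Gram matrix
            G = S.T @ S
            if not np.any(G):
                raise ConvergenceError(
                    f"PLS component {a + 1}: X residual carries no covariance with Y "
                    "(constant or rank-deficient X)"
                )
            v = np.linalg.eigh(G)[1][:, -1]
            u = Y @ v
            w = None
            for _ in range(max_iter):
                w_new = X.T @ u
                nw = np.linalg.norm(w_new)
                if nw <= 0:
                    raise ConvergenceError(
                        f"PLS component {a + 1}: degenerate weight update"
                    )
                w_new /= nw
                if w is not None and np.linalg.norm(w_new - w) <= tol:
                    w = w_new
                    break
                w = w_new
                t = X @ w
                q = Y.T @ t / (t @ t)
                u = Y @ q / (q @ q)
            else:
                raise ConvergenceError(
                    f"PLS component {a + 1} did not converge in {max_iter} iterations"
                )
        sign = _flip_signs(w)
        w *= sign
        t = X @ w
        tt = t @ t
        if tt <= 0:
            raise ConvergenceError(f"PLS component {a + 1}: zero-variance score")
        p_load = X.T @ t / tt
        q_load = Y.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q_load)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q_load, t
    return W, P, Q, T


def pls_coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Regression matrix B = W (P'W)^-1 Q' mapping centred X to centred Y."""
    return W @ np.linalg.solve(P.T @ W, Q.T)


def pls_nested_predictions(
    W: np.ndarray, P: np.ndarray, Q: np.ndarray, Xc_new: np.ndarray
) -> np.ndarray:
    """Centred-scale predictions at every component count 1..A.

    Returns an (A, n_new, m) array; entry ``k-1`` is the prediction of the
    k-component model.  Uses the same deflation recursion as fitting, so it
    is exactly the scores-path prediction.
    """
    A = W.shape[1]
    Xd = np.array(Xc_new, dtype=float)
    out = np.empty((A, Xd.shape[0], Q.shape[0]))
    acc = np.zeros((Xd.shape[0], Q.shape[0]))
    for a in range(A):
        t = Xd @ W[:, a]
        acc = acc + np.outer(t, Q[:, a])
        Xd -= np.outer(t, P[:, a])
        out[a] = acc
    return out


def pcr_svd(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """PCA of centred X by SVD + least squares of Y on the scores.

    Returns (V, C, T): V (p x A) loadings, C (A x m) per-component regression
    coefficients, T (n x A) scores.  Components whose singular value falls
    below ``n * eps * s_max`` contribute nothing (their coefficient row is
    zero), which keeps saturated fits stable on rank-deficient data.
    """
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components > s.size:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_columns)={s.size}"
        )
    signs = np.array([_flip_signs(Vt[a]) for a in range(n_components)])
    V = (Vt[:n_components] * signs[:, None]).T
    U = U[:, :n_components] * signs[None, :]
    s = s[:n_components]
    cutoff = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    inv_s = np.where(s > cutoff, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    C = inv_s[:, None] * (U.T @ Yc)
    T = U * s[None, :]
    return V, C, T


def pcr_nested_predictions(V: np.ndarray, C: np.ndarray, Xc_new: np.ndarray) -> np.ndarray:
    """Centred-scale PCR predictions at every component count 1..A."""
    T_new = Xc_new @ V  # n_new x A
    A = V.shape[1]
    out = np.empty((A, Xc_new.shape[0], C.shape[1]))
    acc = np.zeros((Xc_new.shape[0], C.shape[1]))
    for a in range(A):
        acc = acc + np.outer(T_new[:, a], C[a])
        out[a] = acc
    return out


# ---------------------------------------------------------------------------
# model-level fitting
# ---------------------------------------------------------------------------

def _resolve_mask(grid: WavelengthGrid, wavelength_mask) -> np.ndarray:
    if wavelength_mask is None:
        return np.ones(grid.n_points, dtype=bool)
    mask = np.asarray(wavelength_mask, dtype=bool)
    if mask.shape != (grid.n_points,):
        raise ValueError(
            f"wavelength mask has shape {mask.shape}, expected ({grid.n_points},)"
        )
    if not mask.any():
        raise ValueError("wavelength mask selects no columns")
    return mask


def _prepare(X: SpectraMatrix, Y: ConcentrationMatrix, n_lv, preprocess, wavelength_mask):
    X, Y = align_blocks(X, Y)
    mask = _resolve_mask(X.grid, wavelength_mask)
    Xm = X.absorbance[:, mask]
    n, p = Xm.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv={n_lv} outside valid range 1..{min(n - 1, p)} "
            f"(n_samples={n}, n_masked_wavelengths={p})"
        )
    xp = fit_preprocess(Xm, preprocess)
    yp = fit_preprocess(Y.values, preprocess)
    return X, Y, mask, apply_preprocess(xp, Xm), apply_preprocess(yp, Y.values), xp, yp


def fit_pcr(
    X: SpectraMatrix,
    Y: ConcentrationMatrix,
    n_components: int,
    preprocess: str = "mean_center",
    wavelength_mask=None,
) -> CalibrationModel:
    """Principal component regression of Y on X with ``n_components`` PCs."""
    X, Y, mask, Xc, Yc, xp, yp = _prepare(X, Y, n_components, preprocess, wavelength_mask)
    V, C, T = pcr_svd(Xc, Yc, n_components)
    return CalibrationModel(
        algorithm="PCR",
        n_lv=n_components,
        x_preprocess=xp,
        y_preprocess=yp,
        grid=X.grid,
        wavelength_mask=mask,
        analyte_names=Y.analyte_names,
        x_loadings=V,
        x_scores=T,
        y_loadings=C.T,
        coefficients=V @ C,
    )


def fit_pls(
    X: SpectraMatrix,
    Y: ConcentrationMatrix,
    n_lv: int,
    preprocess: str = "mean_center",
    mode: str = "joint",
    wavelength_mask=None,
) -> CalibrationModel:
    """NIPALS PLS of Y on X with ``n_lv`` latent variables.

    ``mode="joint"`` models all analytes with one decomposition (PLS2, the
    default); ``mode="per_analyte"`` fits an independent PLS1 model per
    column and assembles the coefficient matrix column-wise.
    """
    if mode not in ("joint", "per_analyte"):
        raise ValueError(f"mode must be 'joint' or 'per_analyte', got {mode!r}")
    X, Y, mask, Xc, Yc, xp, yp = _prepare(X, Y, n_lv, preprocess, wavelength_mask)
    if mode == "joint":
        W, P, Q, T = pls_nipals(Xc, Yc, n_lv)
        coef = pls_coefficients(W, P, Q)
    else:
        cols = []
        W = P = Q = T = None  # per-analyte decompositions are not stacked
        for k in range(Yc.shape[1]):
            Wk, Pk, Qk, _ = pls_nipals(Xc, Yc[:, k : k + 1], n_lv)
            cols.append(pls_coefficients(Wk, Pk, Qk)[:, 0])
        coef = np.column_stack(cols)
    return CalibrationModel(
        algorithm="PLS",
        n_lv=n_lv,
        x_preprocess=xp,
        y_preprocess=yp,
        grid=X.grid,
        wavelength_mask=mask,
        analyte_names=Y.analyte_names,
        x_loadings=P,
        x_scores=T,
        y_loadings=None if Q is None else Q,
        weights=W,
        coefficients=coef,
        mode=mode,
    )


def _masked_preprocessed(model: CalibrationModel, X_new: SpectraMatrix) -> np.ndarray:
    if (
        abs(X_new.grid.start_nm - model.grid.start_nm) > 1e-9
        or abs(X_new.grid.end_nm - model.grid.end_nm) > 1e-9
        or abs(X_new.grid.step_nm - model.grid.step_nm) > 1e-9
    ):
        raise ValueError(
            f"grid mismatch: model fitted on ({model.grid.start_nm}, "
            f"{model.grid.end_nm}, {model.grid.step_nm}), data on "
            f"({X_new.grid.start_nm}, {X_new.grid.end_nm}, {X_new.grid.step_nm})"
        )
    return apply_preprocess(model.x_preprocess, X_new.absorbance[:, model.wavelength_mask])


def predict(model: CalibrationModel, X_new: SpectraMatrix) -> ConcentrationMatrix:
    """Predict concentrations (ug/mL) via the coefficient matrix.

    Preprocessing uses the stored calibration parameters; the wavelength mask
    is applied internally, so columns outside it never influence the result.
    """
    Xc = _masked_preprocessed(model, X_new)
    Yc = Xc @ model.coefficients
    return ConcentrationMatrix(
        X_new.sample_ids, model.analyte_names, invert_center(model.y_preprocess, Yc)
    )


def predict_via_scores(model: CalibrationModel, X_new: SpectraMatrix) -> ConcentrationMatrix:
    """Prediction through the latent-space recursion (cross-check path).

    Must agree with :func:`predict` to high precision on any input; joint
    mode only (per-analyte models keep no stacked decomposition).
    """
    Xc = _masked_preprocessed(model, X_new)
    if model.algorithm == "PCR":
        Yc = pcr_nested_predictions(model.x_loadings, model.y_loadings.T, Xc)[-1]
    elif model.mode == "joint":
        Yc = pls_nested_predictions(model.weights, model.x_loadings, model.y_loadings, Xc)[-1]
    else:
        raise ValueError("scores-path prediction requires a joint-mode model")
    return ConcentrationMatrix(
        X_new.sample_ids, model.analyte_names, invert_center(model.y_preprocess, Yc)
    )


# ---------------------------------------------------------------------------
# persistence: a YAML + CSV bundle holding everything prediction needs
# ---------------------------------------------------------------------------

def save_model(model: CalibrationModel, directory) -> None:
    """Serialize a fitted model to ``directory`` as ``model.yaml`` + CSVs.

    The bundle stores the metadata, preprocessing parameters, wavelength mask
    and coefficient matrix — sufficient for prediction.  Latent-space arrays
    (scores, loadings, weights) are fitting artefacts and are not persisted.
    """
    import pathlib

    import pandas as pd
    import yaml

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "mvcalib-model/1",
        "algorithm": model.algorithm,
        "mode": model.mode,
        "n_lv": int(model.n_lv),
        "preprocess": model.x_preprocess.method,
        "analytes": list(model.analyte_names),
        "grid": {
            "start_nm": model.grid.start_nm,
            "end_nm": model.grid.end_nm,
            "step_nm": model.grid.step_nm,
        },
    }
    with open(directory / "model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    wl = model.grid.values()
    pd.DataFrame({"wavelength_nm": wl, "selected": model.wavelength_mask.astype(int)}).to_csv(
        directory / "mask.csv", index=False
    )
    coef = pd.DataFrame(
        model.coefficients, columns=list(model.analyte_names)
    )
    coef.insert(0, "wavelength_nm", wl[model.wavelength_mask])
    coef.to_csv(directory / "coefficients.csv", index=False, float_format="%.12g")
    pre = {"block": [], "role": [], "value": []}
    for block, params in (("x", model.x_preprocess), ("y", model.y_preprocess)):
        if params.column_means is not None:
            for v in params.column_means:
                pre["block"].append(block), pre["role"].append("mean"), pre["value"].append(v)
        if params.column_sds is not None:
            for v in params.column_sds:
                pre["block"].append(block), pre["role"].append("sd"), pre["value"].append(v)
    pd.DataFrame(pre).to_csv(directory / "preprocess.csv", index=False, float_format="%.12g")


def load_model(directory) -> CalibrationModel:
    """Load a model bundle written by :func:`save_model` (prediction-ready)."""
    import pathlib

    import pandas as pd
    import yaml

    directory = pathlib.Path(directory)
    with open(directory / "model.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format") != "mvcalib-model/1":
        raise ValueError(f"{directory}: not an mvcalib model bundle")
    grid = WavelengthGrid(**meta["grid"])
    mask = pd.read_csv(directory / "mask.csv")["selected"].to_numpy(dtype=bool)
    coef_df = pd.read_csv(directory / "coefficients.csv")
    coef = coef_df[meta["analytes"]].to_numpy(dtype=float)
    pre = pd.read_csv(directory / "preprocess.csv")
    method = meta["preprocess"]

    def params_for(block: str) -> PreprocessParams:
        sub = pre[pre["block"] == block]
        means = sub[sub["role"] == "mean"]["value"].to_numpy(dtype=float)
        sds = sub[sub["role"] == "sd"]["value"].to_numpy(dtype=float)
        return PreprocessParams(
            method,
            column_means=means if means.size else None,
            column_sds=sds if sds.size else None,
        )

    return CalibrationModel(
        algorithm=meta["algorithm"],
        n_lv=int(meta["n_lv"]),
        x_preprocess=params_for("x"),
        y_preprocess=params_for("y"),
        grid=grid,
        wavelength_mask=mask,
        analyte_names=tuple(meta["analytes"]),
        coefficients=coef,
        mode=meta.get("mode", "joint"),
    )
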