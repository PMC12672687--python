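"""Column-wise preprocessing with train-fitted, stored parameters.

Parameters are always estimated on calibration (training) data only and then
applied unchanged to new data — the contract that prevents train/test leakage
inside cross-validation.  Methods: ``none``, ``mean_center`` (the default for
latent-variable regression, which needs a centred X/Y for scores to be
variance/covariance directions), and ``autoscale`` (centre then scale each
column to unit SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["METHODS", "PreprocessParams", "fit_preprocess", "apply_preprocess", "invert_center"]

METHODS = ("none", "mean_center", "autoscale")


@dataclass(frozen=True)
class PreprocessParams:
    method: str
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def n_columns(self) -> int | None:
        return None if self.column_means is None else self.column_means.size


def fit_preprocess(X: np.ndarray, method: str = "mean_center") -> PreprocessParams:
    """Estimate per-column preprocessing parameters from the training block.

    ``X`` is any samples x columns array (absorbances or concentrations).
    Autoscale uses the n-1 (sample) standard deviation and rejects
    zero-variance columns, naming the first offending column index.
    """
    if method not in METHODS:
        raise ValueError(f"unknown preprocessing method {method!r}; choose from {METHODS}")
    X = np.asarray(X, dtype=float)
    if method == "none":
        return PreprocessParams("none")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit preprocessing")
    means = X.mean(axis=0)
    if method == "mean_center":
        return PreprocessParams("mean_center", column_means=means)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        col = int(np.flatnonzero(sds <= 0)[0])
        raise ValueError(f"autoscale impossible: column {col} has zero variance")
    return PreprocessParams("autoscale", column_means=means, column_sds=sds)


def _check_width(params: PreprocessParams, X: np.ndarray) -> None:
    if params.method != "none" and X.shape[-1] != params.n_columns:
        raise ValueError(
            f"data has {X.shape[-1]} columns but parameters were fitted on "
            f"{params.n_columns}"
        )


def apply_preprocess(params: PreprocessParams, X: np.ndarray) -> np.ndarray:
    """Transform with *stored* parameters; never re-estimates from ``X``."""
    X = np.asarray(X, dtype=float)
    _check_width(params, X)
    if params.method == "none":
        return X.copy()
    Xc = X - params.column_means
    if params.method == "autoscale":
        Xc /= params.column_sds
    return Xc


def invert_center(params: PreprocessParams, Y: np.ndarray) -> np.ndarray:
    """Back-transform predictions to original units (exact inverse of apply)."""
    Y = np.asarray(Y, dtype=float)
    _check_width(params, Y)
    if params.method == "none":
        return Y.copy()
    if params.method == "autoscale":
        return Y * params.column_sds + params.column_means
    return Y + params.column_means
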