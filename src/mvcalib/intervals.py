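"""Synergy-interval PLS (siPLS) wavelength selection.

The wavelength axis is cut into equidistant intervals; PLS models are
cross-validated on the concatenated columns of every combination of 2, 3
and/or 4 intervals, and combinations are ranked by pooled RMSECV.  The
search is exhaustive over the requested combination sizes, so the winning
spectral regions are a global optimum of the tested family rather than a
heuristic pick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import ConcentrationMatrix, SpectraMatrix, align_blocks
from .validate import CvScheme, make_folds, oof_predictions, _rmse_curves

__all__ = [
    "IntervalScheme",
    "SiplsResult",
    "partition_intervals",
    "enumerate_combinations",
    "mask_from_combination",
    "sipls_search",
]

#: default interval count for the packaged search
DEFAULT_N_INTERVALS = 16


@dataclass(frozen=True)
class IntervalScheme:
    """Equidistant partition of ``n_columns`` grid columns into intervals.

    ``boundaries[i]`` is the half-open column range ``(start, end)`` of
    interval ``i+1`` (intervals are 1-based outside this class).  With
    ``r = L mod n`` the first ``r`` intervals hold ``ceil(L/n)`` columns and
    the rest ``floor(L/n)``, so sizes differ by at most one column.
    """

    n_intervals: int
    n_columns: int
    boundaries: tuple[tuple[int, int], ...]

    def sizes(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.boundaries)


def partition_intervals(n_columns: int, n_intervals: int) -> IntervalScheme:
    """Cut ``n_columns`` grid columns into ``n_intervals`` contiguous pieces."""
    if not (1 <= n_intervals <= n_columns):
        raise ValueError(
            f"n_intervals must be in 1..{n_columns} (number of columns), got {n_intervals}"
        )
    base, r = divmod(n_columns, n_intervals)
    bounds = []
    start = 0
    for i in range(n_intervals):
        width = base + (1 if i < r else 0)
        bounds.append((start, start + width))
        start += width
    return IntervalScheme(n_intervals, n_columns, tuple(bounds))


def enumerate_combinations(n_intervals: int, sizes) -> list[tuple[int, ...]]:
    """All size-k subsets of the 1-based interval indices, for each k in sizes."""
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise ValueError("sizes must be a nonempty subset of {2, 3, 4}")
    if any(s not in (2, 3, 4) for s in sizes):
        raise ValueError(f"combination sizes must be within {{2, 3, 4}}, got {sizes}")
    out: list[tuple[int, ...]] = []
    for k in sizes:
        out.extend(itertools.combinations(range(1, n_intervals + 1), k))
    return out


def mask_from_combination(scheme: IntervalScheme, combination) -> np.ndarray:
    """Boolean column mask selecting exactly the union of the named intervals."""
    combo = tuple(int(i) for i in combination)
    if not combo:
        raise ValueError("empty interval combination")
    mask = np.zeros(scheme.n_columns, dtype=bool)
    for i in combo:
        if not (1 <= i <= scheme.n_intervals):
            raise ValueError(
                f"interval index {i} out of range 1..{scheme.n_intervals}"
            )
        s, e = scheme.boundaries[i - 1]
        mask[s:e] = True
    return mask


@dataclass(frozen=True, order=False)
class SiplsResult:
    """One (interval combination, LV count) candidate from the search."""

    combination: tuple[int, ...]  # sorted 1-based interval indices
    n_lv: int
    rmsecv: float  # pooled across analytes, ug/mL
    per_analyte_rmsecv: tuple[float, ...]
    rank: int = 0
    skipped_lvs: tuple[int, ...] = ()  # LV counts infeasible for this combination


def _sort_key(res: SiplsResult):
    return (res.rmsecv, res.n_lv, res.combination)


def sipls_search(
    X: SpectraMatrix,
    Y: ConcentrationMatrix,
    scheme: IntervalScheme,
    sizes=(2, 3, 4),
    max_lv: int = 10,
    cv_scheme: CvScheme = CvScheme("leave_one_out"),
    preprocess: str = "mean_center",
    mode: str = "joint",
) -> list[SiplsResult]:
    """Exhaustive siPLS search, ranked by ascending pooled RMSECV.

    For every interval combination a joint PLS model is cross-validated on
    the concatenated columns at each LV count 1..max_lv (counts infeasible
    for a combination — more LVs than columns or training samples allow —
    are skipped and recorded).  Each combination contributes its best LV
    count; ties break toward fewer LVs, then lexicographic combination.
    """
    X, Y = align_blocks(X, Y)
    if X.grid.n_points != scheme.n_columns:
        raise ValueError(
            f"interval scheme covers {scheme.n_columns} columns but spectra have "
            f"{X.grid.n_points}"
        )
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    Xa, Yv = X.absorbance, Y.values
    folds = make_folds(cv_scheme, X.n_samples)
    min_train = min(tr.size for tr, _ in folds)
    slices = [slice(s, e) for s, e in scheme.boundaries]
    results = []
    for combo in enumerate_combinations(scheme.n_intervals, sizes):
        Xsub = np.concatenate([Xa[:, slices[i - 1]] for i in combo], axis=1)
        bound = min(min_train - 1, Xsub.shape[1])
        eff_lv = min(max_lv, bound)
        skipped = tuple(range(eff_lv + 1, max_lv + 1))
        if eff_lv < 1:
            continue  # no feasible model for this combination
        preds, _ = oof_predictions(
            Xsub, Yv, folds, eff_lv, algorithm="pls", preprocess=preprocess, mode=mode
        )
        per_analyte, pooled = _rmse_curves(preds, Yv)
        best = int(np.argmin(pooled))  # ties -> smaller LV count (first argmin)
        results.append(
            SiplsResult(
                combination=combo,
                n_lv=best + 1,
                rmsecv=float(pooled[best]),
                per_analyte_rmsecv=tuple(float(v) for v in per_analyte[best]),
                skipped_lvs=skipped,
            )
        )
    results.sort(key=_sort_key)
    return [
        SiplsResult(
            combination=r.combination,
            n_lv=r.n_lv,
            rmsecv=r.rmsecv,
            per_analyte_rmsecv=r.per_analyte_rmsecv,
            rank=i + 1,
            skipped_lvs=r.skipped_lvs,
        )
        for i, r in enumerate(results)
    ]
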