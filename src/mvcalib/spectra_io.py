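"""Wavelength grids, absorbance matrices and concentration tables.

All downstream modules operate on three containers defined here:

``WavelengthGrid``
    the discretised wavelength axis (nm) every spectrum lives on;
``SpectraMatrix``
    samples x wavelengths absorbances in AU (the X block);
``ConcentrationMatrix``
    samples x analytes concentrations in ug/mL (the Y block).

CSV interchange uses comma separation, ``.`` decimals, UTF-8 and a mandatory
header row.  Spectra files carry the wavelengths (1 decimal place) in the
header and one row per sample, first column the sample id.  Concentration
files carry analyte names in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraMatrix",
    "ConcentrationMatrix",
    "build_wavelength_grid",
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
]

#: tolerance (nm) for matching wavelength headers against a grid
WAVELENGTH_TOL_NM = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis from ``start_nm`` to ``end_nm`` inclusive."""

    start_nm: float
    end_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if not (self.step_nm > 0):
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        residual = abs(span - round(span))
        if residual > 1e-6:
            raise ValueError(
                "wavelength range is not an integer multiple of the step: "
                f"(end - start)/step = {span!r} deviates from an integer by "
                f"{residual:.3e}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def values(self) -> np.ndarray:
        """Grid wavelengths in nm, strictly increasing, evenly spaced."""
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


def build_wavelength_grid(start_nm: float, end_nm: float, step_nm: float) -> WavelengthGrid:
    """Construct a :class:`WavelengthGrid`, validating commensurability.

    The canonical UV axis used throughout the package is
    ``build_wavelength_grid(220.0, 400.0, 0.1)`` -> 1801 points.
    """
    return WavelengthGrid(float(start_nm), float(end_nm), float(step_nm))


def _check_sample_ids(sample_ids: tuple[str, ...]) -> None:
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")


@dataclass(frozen=True)
class SpectraMatrix:
    """Absorbance block: ``absorbance[i, j]`` is sample *i* at grid point *j* (AU)."""

    sample_ids: tuple[str, ...]
    grid: WavelengthGrid
    absorbance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_sample_ids(self.sample_ids)
        if ab.ndim != 2:
            raise ValueError("absorbance must be a 2-D samples x wavelengths array")
        if ab.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {ab.shape[0]} spectra rows"
            )
        if ab.shape[1] != self.grid.n_points:
            raise ValueError(
                f"spectra have {ab.shape[1]} columns but grid has "
                f"{self.grid.n_points} points"
            )
        if not np.all(np.isfinite(ab)):
            bad = np.argwhere(~np.isfinite(ab))[0]
            raise ValueError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]!r}, "
                f"grid column {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def select_samples(self, ids) -> "SpectraMatrix":
        """Row subset by sample id, preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        ids = [str(s) for s in ids]
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not present: {missing}")
        rows = [index[s] for s in ids]
        return SpectraMatrix(tuple(ids), self.grid, self.absorbance[rows])


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Concentration block: ``values[i, k]`` is analyte *k* of sample *i* (ug/mL)."""

    sample_ids: tuple[str, ...]
    analyte_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(
            self, "analyte_names", tuple(str(a) for a in self.analyte_names)
        )
        _check_sample_ids(self.sample_ids)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D samples x analytes array")
        if vals.shape != (len(self.sample_ids), len(self.analyte_names)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analyte_names)} analytes"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite concentration value")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def select_samples(self, ids) -> "ConcentrationMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        ids = [str(s) for s in ids]
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not present: {missing}")
        rows = [index[s] for s in ids]
        return ConcentrationMatrix(tuple(ids), self.analyte_names, self.values[rows])


def align_blocks(
    X: SpectraMatrix, Y: ConcentrationMatrix
) -> tuple[SpectraMatrix, ConcentrationMatrix]:
    """Align an X/Y pair by sample id (Y reordered to X's order).

    Alignment is by id, never by position, so a shuffled concentration file
    cannot be silently paired with the wrong spectra.
    """
    if set(X.sample_ids) != set(Y.sample_ids):
        only_x = sorted(set(X.sample_ids) - set(Y.sample_ids))
        only_y = sorted(set(Y.sample_ids) - set(X.sample_ids))
        raise ValueError(
            f"sample id mismatch between spectra and concentrations: "
            f"only in spectra {only_x}, only in concentrations {only_y}"
        )
    return X, Y.select_samples(X.sample_ids)


def _infer_grid(wavelengths: np.ndarray) -> WavelengthGrid:
    if wavelengths.size < 2:
        raise ValueError("need at least two wavelength columns to infer a grid")
    diffs = np.diff(wavelengths)
    if np.any(diffs <= 0):
        raise ValueError("wavelength header is not strictly increasing")
    step = float(np.median(diffs))
    if np.max(np.abs(diffs - step)) > WAVELENGTH_TOL_NM:
        raise ValueError("wavelength header is not evenly spaced")
    return WavelengthGrid(float(wavelengths[0]), float(wavelengths[-1]), step)


def read_spectra(path, grid: WavelengthGrid | None = None) -> SpectraMatrix:
    """Read a spectra CSV (``sample_id,220.0,220.1,...,400.0``).

    The wavelength header must match ``grid`` (within 1e-6 nm) when one is
    given; otherwise an evenly spaced grid is inferred from the header.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength header: {exc}") from None
    if df.isna().any().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing/non-numeric cell at sample {df.index[row]!r}, "
            f"wavelength {df.columns[col]}"
        )
    if grid is None:
        grid = _infer_grid(wavelengths)
    else:
        if wavelengths.size != grid.n_points or np.max(
            np.abs(wavelengths - grid.values())
        ) > WAVELENGTH_TOL_NM:
            raise ValueError(f"{path}: wavelength header does not match declared grid")
    values = df.to_numpy(dtype=float)
    return SpectraMatrix(tuple(str(s) for s in df.index), grid, values)


def write_spectra(matrix: SpectraMatrix, path) -> None:
    """Write a spectra CSV; round-trips through :func:`read_spectra` to 12 sig. digits."""
    header = [f"{w:.1f}" for w in matrix.grid.values()]
    df = pd.DataFrame(matrix.absorbance, index=list(matrix.sample_ids), columns=header)
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def read_concentrations(path) -> ConcentrationMatrix:
    """Read a concentration CSV (``sample_id,<analyte>,...``); values must be > 0."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty concentration table")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()].astype(str)))
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    if df.isna().any().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing/non-numeric cell at sample {df.index[row]!r}, "
            f"analyte {df.columns[col]!r}"
        )
    values = df.to_numpy(dtype=float)
    if np.any(values <= 0):
        row, col = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"{path}: non-positive concentration at sample {df.index[row]!r}, "
            f"analyte {df.columns[col]!r}"
        )
    return ConcentrationMatrix(
        tuple(str(s) for s in df.index), tuple(df.columns), values
    )


def write_concentrations(matrix: ConcentrationMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=list(matrix.sample_ids), columns=list(matrix.analyte_names)
    )
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")
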