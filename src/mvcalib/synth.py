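"""Synthetic UV spectra: Gaussian-band pure components, Beer-Lambert mixtures.

The four default pure components are stand-ins for safinamide, its precursor
impurity and its two degradation products: sums of 2-3 Gaussian bands chosen
so that the unit spectra are severely overlapped (pairwise Pearson |r| > 0.5
over the 220-400 nm grid) with all absorption maxima between 220 and 320 nm,
the qualitative situation that makes univariate quantification impossible and
motivates multivariate calibration.

Mixtures obey Beer-Lambert additivity, X = C.S, with optional i.i.d. Gaussian
photometric noise and a per-sample random linear baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import ConcentrationMatrix, SpectraMatrix, WavelengthGrid

__all__ = [
    "PureComponentModel",
    "NoiseModel",
    "default_pure_components",
    "pure_spectrum",
    "unit_spectra",
    "simulate_mixtures",
    "random_design",
]

#: default additive photometric noise, AU (typical bench double-beam instrument)
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class PureComponentModel:
    """Pure-component absorptivity curve as a sum of Gaussian bands.

    Each band is ``(center_nm, width_nm, absorptivity_peak)`` with width the
    Gaussian sigma and peak absorptivity in AU.mL/ug, so the unit-concentration
    spectrum is non-negative everywhere by construction.
    """

    analyte_name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a pure component needs at least one band")
        for center, width, peak in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
            if peak <= 0:
                raise ValueError(f"peak absorptivity must be > 0, got {peak}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise: white Gaussian noise plus linear baseline drift.

    ``additive_sd`` is the per-point noise SD in AU; ``baseline_slope_sd`` the
    SD of a per-sample random baseline slope, in AU per 100 nm.
    """

    additive_sd: float = DEFAULT_NOISE_SD
    baseline_slope_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.baseline_slope_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


# Band parameters (center nm, sigma nm, peak absorptivity AU.mL/ug) for the
# four default components.  A shared strong end-absorption band near 225 nm
# plus distinct secondary bands gives the required severe overlap while
# keeping the four curves linearly independent.
_DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "SAF": ((226.0, 10.0, 0.050), (265.0, 16.0, 0.028)),
    "HBD": ((228.0, 11.0, 0.085), (284.0, 13.0, 0.055)),
    "HYD": ((231.0, 12.0, 0.065), (258.0, 15.0, 0.030)),
    "OXD": ((225.0, 9.0, 0.048), (249.0, 13.0, 0.030), (295.0, 18.0, 0.012)),
}


def default_pure_components(grid: WavelengthGrid) -> tuple[PureComponentModel, ...]:
    """The four fixed pure-component band models (deterministic constants)."""
    centers = [c for bands in _DEFAULT_BANDS.values() for c, _, _ in bands]
    if grid.start_nm > min(centers) or grid.end_nm < max(centers):
        raise ValueError(
            f"grid [{grid.start_nm}, {grid.end_nm}] nm does not span the band set "
            f"[{min(centers)}, {max(centers)}] nm"
        )
    return tuple(
        PureComponentModel(name, bands) for name, bands in _DEFAULT_BANDS.items()
    )


def pure_spectrum(
    model: PureComponentModel, grid: WavelengthGrid, concentration: float
) -> np.ndarray:
    """Beer-Lambert spectrum of one component at ``concentration`` ug/mL.

    Exactly linear in concentration: doubling the concentration doubles every
    point, and zero concentration gives the zero vector.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    wl = grid.values()
    spec = np.zeros_like(wl)
    for center, width, peak in model.bands:
        spec += peak * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return concentration * spec


def unit_spectra(
    models, grid: WavelengthGrid
) -> np.ndarray:
    """Stack unit-concentration spectra into an analytes x wavelengths matrix S."""
    return np.array([pure_spectrum(m, grid, 1.0) for m in models])


def simulate_mixtures(
    models,
    design: ConcentrationMatrix,
    grid: WavelengthGrid,
    noise: NoiseModel | None = None,
) -> SpectraMatrix:
    """Simulate mixture spectra X = C.S + noise + drift for a design.

    ``models`` must carry exactly the design's analytes (same order).  With
    ``noise=None`` (or zero SDs) each row is the exact linear combination of
    pure spectra; identical seeds give bit-identical matrices.
    """
    model_names = tuple(m.analyte_name for m in models)
    if model_names != design.analyte_names:
        raise ValueError(
            f"analyte mismatch: models {model_names} vs design {design.analyte_names}"
        )
    S = unit_spectra(models, grid)
    X = design.values @ S
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.additive_sd > 0:
            X = X + rng.normal(0.0, noise.additive_sd, size=X.shape)
        if noise.baseline_slope_sd > 0:
            slopes = rng.normal(0.0, noise.baseline_slope_sd, size=X.shape[0])
            ramp = (grid.values() - grid.start_nm) / 100.0  # AU per 100 nm
            X = X + slopes[:, None] * ramp[None, :]
    return SpectraMatrix(design.sample_ids, grid, X)


def random_design(
    n_samples: int,
    level_sets: dict[str, tuple[float, ...]],
    seed: int,
    sample_prefix: str = "S",
) -> ConcentrationMatrix:
    """Random multilevel design: each cell drawn uniformly from its level set."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for name, levels in level_sets.items():
        if len(levels) < 2:
            raise ValueError(f"analyte {name!r} needs at least 2 levels")
    rng = np.random.default_rng(seed)
    analytes = tuple(level_sets)
    cols = [
        rng.choice(np.asarray(level_sets[name], dtype=float), size=n_samples)
        for name in analytes
    ]
    values = np.column_stack(cols)
    ids = tuple(f"{sample_prefix}{i + 1}" for i in range(n_samples))
    return ConcentrationMatrix(ids, analytes, values)
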