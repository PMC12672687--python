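"""End-to-end simulation studies on synthetic mixtures.

Two replicated studies summarise what the calibration stack delivers under
controlled conditions:

* :func:`recovery_study` — simulate the packaged 25-mixture design with
  photometric noise, fit PCR, full-spectrum PLS and siPLS (latent variables
  chosen by leave-one-out RMSECV), and score each replicate on the external
  validation set: every analyte's mean recovery must lie in [98, 102]% with
  RSD < 3%.
* :func:`interval_benefit_study` — simulate mixtures whose analytical signal
  is confined to two wavelength intervals while the rest of the axis is
  noise-only, and check that siPLS-selected models predict at least as well
  as full-spectrum PLS at the same number of latent variables.

Replicate seeds are spawned deterministically from one base seed, so every
study is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MixtureDesign, split_design, table1_design
from .intervals import IntervalScheme, mask_from_combination, partition_intervals, sipls_search
from .regression import CalibrationModel, fit_pcr, fit_pls, predict
from .spectra_io import SpectraMatrix, WavelengthGrid, build_wavelength_grid
from .synth import NoiseModel, PureComponentModel, default_pure_components, simulate_mixtures
from .validate import CvScheme, cross_validate, recovery_stats, rmse, select_lv

__all__ = [
    "simulate_design_run",
    "fit_three_models",
    "recovery_study",
    "RecoveryStudyResult",
    "localized_pure_components",
    "interval_benefit_study",
    "IntervalBenefitResult",
]

#: recovery acceptance window (%) and RSD ceiling (%) per analyte
RECOVERY_WINDOW = (98.0, 102.0)
RSD_LIMIT = 3.0

MODEL_NAMES = ("PCR", "PLS", "siPLS")


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def simulate_design_run(
    seed: int,
    noise_sd: float = 0.002,
    baseline_slope_sd: float = 0.0,
    design: MixtureDesign | None = None,
    models: tuple[PureComponentModel, ...] | None = None,
    grid: WavelengthGrid | None = None,
):
    """Simulate one calibration/validation campaign.

    Returns ``(Xcal, Ycal, Xval, Yval)`` for the given design (default: the
    packaged 25-mixture design on the 220-400 nm / 0.1 nm grid with the four
    default pure components).
    """
    if grid is None:
        grid = build_wavelength_grid(220.0, 400.0, 0.1)
    if design is None:
        design = table1_design()
    if models is None:
        models = default_pure_components(grid)
    noise = NoiseModel(noise_sd, baseline_slope_sd, seed=seed)
    X = simulate_mixtures(models, design.concentrations, grid, noise)
    Ycal, Yval = split_design(design)
    return (
        X.select_samples(design.calibration_ids),
        Ycal,
        X.select_samples(design.validation_ids),
        Yval,
    )


def fit_three_models(
    Xcal: SpectraMatrix,
    Ycal,
    max_lv_full: int = 8,
    n_intervals: int = 16,
    sipls_sizes=(2, 3, 4),
    sipls_max_lv: int = 5,
    cv: CvScheme = CvScheme("leave_one_out"),
) -> dict[str, CalibrationModel]:
    """Fit PCR, full-spectrum PLS and siPLS with CV-selected latent variables."""
    out: dict[str, CalibrationModel] = {}
    for name, algorithm in (("PCR", "pcr"), ("PLS", "pls")):
        curve = cross_validate(Xcal, Ycal, cv, max_lv_full, algorithm=algorithm)
        n_lv = select_lv(curve.pooled)
        fitter = fit_pcr if algorithm == "pcr" else fit_pls
        out[name] = fitter(Xcal, Ycal, n_lv)
    scheme = partition_intervals(Xcal.grid.n_points, n_intervals)
    ranking = sipls_search(
        Xcal, Ycal, scheme, sizes=sipls_sizes, max_lv=sipls_max_lv, cv_scheme=cv
    )
    best = ranking[0]
    mask = mask_from_combination(scheme, best.combination)
    out["siPLS"] = fit_pls(Xcal, Ycal, best.n_lv, wavelength_mask=mask)
    return out


@dataclass(frozen=True)
class RecoveryStudyResult:
    n_replicates: int
    pass_counts: dict[str, int]  # model name -> replicates meeting the window
    details: pd.DataFrame = field(repr=False)  # per replicate/model/analyte

    def pass_fraction(self, model: str) -> float:
        return self.pass_counts[model] / self.n_replicates


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    noise_sd: float = 0.002,
    max_lv_full: int = 8,
    n_intervals: int = 16,
    sipls_sizes=(2, 3, 4),
    sipls_max_lv: int = 5,
) -> RecoveryStudyResult:
    """Replicated external-validation recovery study on the packaged design."""
    seeds = _spawn_seeds(seed, n_replicates)
    rows = []
    passes = {name: 0 for name in MODEL_NAMES}
    for rep, s in enumerate(seeds):
        Xcal, Ycal, Xval, Yval = simulate_design_run(int(s), noise_sd=noise_sd)
        models = fit_three_models(
            Xcal,
            Ycal,
            max_lv_full=max_lv_full,
            n_intervals=n_intervals,
            sipls_sizes=sipls_sizes,
            sipls_max_lv=sipls_max_lv,
        )
        for name, model in models.items():
            Yhat = predict(model, Xval)
            ok = True
            for k, analyte in enumerate(Yval.analyte_names):
                mean, sd, rsd = recovery_stats(Yhat.values[:, k], Yval.values[:, k])
                ok = ok and RECOVERY_WINDOW[0] <= mean <= RECOVERY_WINDOW[1] and rsd < RSD_LIMIT
                rows.append(
                    {
                        "replicate": rep,
                        "model": name,
                        "analyte": analyte,
                        "n_lv": model.n_lv,
                        "mean_recovery_pct": mean,
                        "rsd_pct": rsd,
                        "rmsep": rmse(Yhat.values[:, k], Yval.values[:, k]),
                    }
                )
            passes[name] += int(ok)
    return RecoveryStudyResult(n_replicates, passes, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# localized-signal benchmark (does interval selection beat the full spectrum?)
# ---------------------------------------------------------------------------

def localized_pure_components(
    grid: WavelengthGrid, scheme: IntervalScheme, signal_intervals: tuple[int, int] = (3, 8)
) -> tuple[PureComponentModel, ...]:
    """Four components whose bands sit strictly inside two chosen intervals.

    Two analytes absorb only inside the first signal interval and two only
    inside the second, so no single interval identifies all four and the
    informative combination is exactly the signal pair.  Everything outside
    those intervals is baseline: with photometric noise and drift added,
    those regions carry no analytical information — the situation where
    interval selection should beat full-spectrum modelling.
    """
    wl = grid.values()
    names = ("SAF", "HBD", "HYD", "OXD")
    peaks = (0.050, 0.080, 0.065, 0.048)
    interval_of = (0, 0, 1, 1)  # first two analytes -> first interval
    band_fracs = ((0.30, 0.65), (0.40, 0.75), (0.30, 0.65), (0.40, 0.75))
    out = []
    for k, name in enumerate(names):
        s, e = scheme.boundaries[signal_intervals[interval_of[k]] - 1]
        lo, hi = wl[s], wl[e - 1]
        span = hi - lo
        sigma = span / 12.0  # bands decay well inside the interval
        bands = tuple(
            (lo + f * span, sigma, p)
            for f, p in zip(band_fracs[k], (peaks[k], 0.6 * peaks[k]))
        )
        out.append(PureComponentModel(name, bands))
    return tuple(out)


@dataclass(frozen=True)
class IntervalBenefitResult:
    n_replicates: int
    wins: int  # replicates where siPLS RMSEP <= full-spectrum PLS RMSEP
    top_hits: int  # replicates where the top size-2 combination is the signal pair
    details: pd.DataFrame = field(repr=False)

    @property
    def win_fraction(self) -> float:
        return self.wins / self.n_replicates


def interval_benefit_study(
    n_replicates: int = 50,
    seed: int = 0,
    noise_sd: float = 0.002,
    baseline_slope_sd: float = 0.005,
    n_intervals: int = 12,
    signal_intervals: tuple[int, int] = (3, 8),
    max_lv: int = 4,
    step_nm: float = 0.5,
) -> IntervalBenefitResult:
    """siPLS vs full-spectrum PLS on localized-signal synthetic mixtures.

    The simulated instrument adds white photometric noise and a per-sample
    linear baseline drift; drift is broadband, so it degrades a full-spectrum
    model far more than one restricted to narrow intervals — the practical
    reason for interval selection.  Per replicate the best size-2 siPLS model
    (leave-one-out RMSECV) fixes both the wavelength mask and the LV count;
    the full-spectrum PLS comparator uses the *same* LV count, and both are
    scored by pooled RMSEP on the external validation samples.
    """
    grid = build_wavelength_grid(220.0, 400.0, step_nm)
    scheme = partition_intervals(grid.n_points, n_intervals)
    models = localized_pure_components(grid, scheme, signal_intervals)
    design = table1_design()
    seeds = _spawn_seeds(seed, n_replicates)
    rows = []
    wins = top_hits = 0
    for rep, s in enumerate(seeds):
        Xcal, Ycal, Xval, Yval = simulate_design_run(
            int(s),
            noise_sd=noise_sd,
            baseline_slope_sd=baseline_slope_sd,
            design=design,
            models=models,
            grid=grid,
        )
        ranking = sipls_search(Xcal, Ycal, scheme, sizes=(2,), max_lv=max_lv)
        best = ranking[0]
        mask = mask_from_combination(scheme, best.combination)
        sipls_model = fit_pls(Xcal, Ycal, best.n_lv, wavelength_mask=mask)
        full_model = fit_pls(Xcal, Ycal, best.n_lv)
        rmsep_si = rmse(predict(sipls_model, Xval).values, Yval.values)
        rmsep_full = rmse(predict(full_model, Xval).values, Yval.values)
        win = rmsep_si <= rmsep_full
        hit = best.combination == tuple(sorted(signal_intervals))
        wins += int(win)
        top_hits += int(hit)
        rows.append(
            {
                "replicate": rep,
                "combination": str(best.combination),
                "n_lv": best.n_lv,
                "rmsep_sipls": rmsep_si,
                "rmsep_full_pls": rmsep_full,
                "sipls_wins": win,
                "signal_pair_top": hit,
            }
        )
    return IntervalBenefitResult(n_replicates, wins, top_hits, pd.DataFrame(rows))
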