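"""The five-level, four-factor mixture design used for calibration.

25 quaternary mixtures of safinamide (SAF), its synthetic precursor impurity
4-hydroxybenzaldehyde (HBD), and its hydrolytic (HYD) and oxidative (OXD)
degradation products, each analyte at five equally spaced concentration
levels.  17 samples form the calibration (training) set and the remaining 8
the external validation set.  The design is balanced: every level of every
analyte occurs in exactly five mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import ConcentrationMatrix

__all__ = [
    "ANALYTES",
    "LEVELS",
    "MixtureDesign",
    "table1_design",
    "split_design",
]

ANALYTES = ("SAF", "HBD", "HYD", "OXD")

#: five design levels per analyte (ug/mL)
LEVELS: dict[str, tuple[float, ...]] = {
    "SAF": (3.0, 8.0, 13.0, 18.0, 23.0),
    "HBD": (1.0, 2.0, 3.0, 4.0, 5.0),
    "HYD": (2.5, 3.5, 4.5, 5.5, 6.5),
    "OXD": (5.0, 7.0, 9.0, 11.0, 13.0),
}

# sample id -> (SAF, HBD, HYD, OXD) in ug/mL; every cell a design level
_DESIGN_ROWS: dict[int, tuple[float, float, float, float]] = {
    1: (13, 3, 4.5, 9),
    2: (13, 1, 2.5, 13),
    3: (3, 1, 6.5, 7),
    4: (3, 5, 3.5, 13),
    5: (23, 2, 6.5, 9),
    6: (8, 5, 4.5, 7),
    7: (23, 3, 3.5, 7),
    8: (13, 2, 3.5, 11),
    9: (8, 2, 5.5, 13),
    10: (8, 4, 6.5, 11),
    11: (18, 5, 5.5, 9),
    12: (23, 4, 4.5, 13),
    13: (18, 3, 6.5, 13),
    14: (13, 5, 6.5, 5),
    15: (23, 5, 2.5, 11),
    16: (23, 1, 5.5, 5),
    17: (3, 4, 2.5, 9),
    18: (18, 1, 4.5, 11),
    19: (3, 3, 5.5, 11),
    20: (13, 4, 5.5, 7),
    21: (18, 4, 3.5, 5),
    22: (18, 2, 2.5, 7),
    23: (8, 1, 3.5, 9),
    24: (3, 2, 4.5, 5),
    25: (8, 3, 2.5, 5),
}

#: external validation samples; the other 17 are the calibration set
_VALIDATION_IDS = (9, 11, 18, 19, 20, 21, 22, 24)

#: cells that could not be transcribed verbatim (none)
RECONSTRUCTED_CELLS: tuple = ()


@dataclass(frozen=True)
class MixtureDesign:
    """A mixture design plus its calibration/validation partition."""

    concentrations: ConcentrationMatrix
    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        cal, val = set(self.calibration_ids), set(self.validation_ids)
        if cal & val:
            raise ValueError(
                f"samples in both calibration and validation sets: {sorted(cal & val)}"
            )
        if cal | val != set(self.concentrations.sample_ids):
            raise ValueError(
                "calibration and validation ids must together cover every design sample"
            )


def table1_design() -> MixtureDesign:
    """The packaged 25-sample design (17 calibration + 8 validation).

    Deterministic constant; the central design point is sample 1 at
    (13, 3, 4.5, 9) ug/mL.
    """
    ids = tuple(str(i) for i in sorted(_DESIGN_ROWS))
    values = np.array([_DESIGN_ROWS[int(i)] for i in ids], dtype=float)
    conc = ConcentrationMatrix(ids, ANALYTES, values)
    val_ids = tuple(str(i) for i in _VALIDATION_IDS)
    cal_ids = tuple(s for s in ids if s not in set(val_ids))
    return MixtureDesign(conc, cal_ids, val_ids)


def split_design(design: MixtureDesign) -> tuple[ConcentrationMatrix, ConcentrationMatrix]:
    """Split a design into (calibration, validation) concentration matrices."""
    cal = design.concentrations.select_samples(design.calibration_ids)
    val = design.concentrations.select_samples(design.validation_ids)
    return cal, val
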