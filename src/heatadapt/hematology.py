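"""Carbon-monoxide rebreathing: hemoglobin mass and intravascular volumes.

A known CO dose (0.8 mL per kg body mass) is rebreathed and dilutes into
circulating carboxyhemoglobin; the rise in HbCO% between baseline and
post-procedure capillary samples, corrected for unabsorbed CO, yields total
hemoglobin mass through the Hufner binding capacity (1.39 mL CO per g Hb).
Blood, red-cell and plasma volumes follow from hemoglobin concentration and
hematocrit with the 0.91 whole-body/venous hematocrit (f-cell) correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HUFNER_ML_CO_PER_G",
    "F_CELL",
    "MCHC_G_DL",
    "RebreatheRecord",
    "HematologyResult",
    "hb_mass_from_rebreathe",
    "intravascular_volumes",
    "typical_error",
]

HUFNER_ML_CO_PER_G = 1.39
F_CELL = 0.91
MCHC_G_DL = 33.0  # mean corpuscular Hb concentration, g per dL of red cells


@dataclass(frozen=True)
class RebreatheRecord:
    """One CO-rebreathing procedure."""

    hbco_pre_pct: float
    hbco_post_pct: float
    hct: float  # hematocrit as a fraction
    co_admin_ml: float  # administered dose, 0.8 mL/kg
    co_unabsorbed_ml: float  # exhaled + end-procedure lung residual
    body_mass_kg: float
    hb_conc_g_dl: float | None = None

    def __post_init__(self):
        if not 0 <= self.hbco_pre_pct < self.hbco_post_pct <= 15:
            raise ValueError("need 0 <= HbCO_pre < HbCO_post <= 15 %")
        if not 0.2 <= self.hct <= 0.6:
            raise ValueError("hematocrit outside 0.2-0.6")
        if self.co_admin_ml <= 0 or self.body_mass_kg <= 0:
            raise ValueError("dose and body mass must be positive")
        if self.co_unabsorbed_ml < 0 or self.co_unabsorbed_ml >= self.co_admin_ml:
            raise ValueError("unabsorbed CO must lie in [0, dose)")


def hb_mass_from_rebreathe(rec: RebreatheRecord, hufner: float = HUFNER_ML_CO_PER_G) -> float:
    """Total hemoglobin mass (g) from the CO dilution.

    hb_mass = absorbed CO * 100 / (delta HbCO * hufner), with delta HbCO in
    percentage points.
    """
    delta = rec.hbco_post_pct - rec.hbco_pre_pct
    if delta <= 0:
        raise ValueError("HbCO did not rise; cannot compute Hb mass")
    co_absorbed = rec.co_admin_ml - rec.co_unabsorbed_ml
    return co_absorbed * 100.0 / (delta * hufner)


@dataclass
class HematologyResult:
    hb_mass_g: float
    hb_mass_g_kg: float
    blood_volume_ml: float
    blood_volume_ml_kg: float
    red_cell_volume_ml: float
    plasma_volume_ml: float
    plasma_volume_ml_kg: float


def intravascular_volumes(
    hb_mass_g: float,
    hct: float,
    hb_conc_g_dl: float | None,
    body_mass_kg: float,
    *,
    f_cell: float = F_CELL,
    mchc_g_dl: float = MCHC_G_DL,
) -> HematologyResult:
    """Blood, red-cell and plasma volumes from Hb mass, hematocrit and [Hb].

    blood volume (mL) = hb_mass / [Hb] * 100; red-cell volume = blood volume
    * hct * f_cell; plasma = blood - red cell. When [Hb] is not measured it
    is reconstructed from hematocrit via an assumed MCHC (33 g/dL of red
    cells) with a warning.
    """
    if hb_mass_g <= 0 or body_mass_kg <= 0:
        raise ValueError("hb mass and body mass must be positive")
    if hb_conc_g_dl is None:
        hb_conc_g_dl = mchc_g_dl * hct * f_cell
        warnings.warn(
            "hemoglobin concentration not provided; derived from hematocrit "
            f"assuming MCHC {mchc_g_dl} g/dL",
            stacklevel=2,
        )
    if hb_conc_g_dl <= 0:
        raise ValueError("hemoglobin concentration must be positive")
    bv = hb_mass_g / hb_conc_g_dl * 100.0
    rcv = bv * hct * f_cell
    pv = bv - rcv
    return HematologyResult(
        hb_mass_g=hb_mass_g,
        hb_mass_g_kg=hb_mass_g / body_mass_kg,
        blood_volume_ml=bv,
        blood_volume_ml_kg=bv / body_mass_kg,
        red_cell_volume_ml=rcv,
        plasma_volume_ml=pv,
        plasma_volume_ml_kg=pv / body_mass_kg,
    )


def typical_error(pairs) -> float:
    """Typical error of duplicate measurements as a coefficient of variation (%).

    TE = SD(differences) / sqrt(2); CV% = 100 * TE / grand mean.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 paired duplicate measurements, shape (n, 2)")
    diffs = arr[:, 0] - arr[:, 1]
    te = diffs.std(ddof=1) / math.sqrt(2.0)
    return 100.0 * te / arr.mean()
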