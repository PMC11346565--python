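"""Partitional calorimetry for exercise-heat-stress trials.

Decomposes human heat exchange during a steady-state exercise bout into
metabolic heat production, external work, dry (convective + radiative)
exchange, respiratory exchange, and the evaporative requirement, and
expresses compensability as the ratio of the evaporation required for heat
balance (Ereq) to the maximum evaporation the environment permits (Emax).
A ratio above 1 marks an uncompensable condition: heat storage is
unavoidable regardless of the sweating response.

Sign convention: every flux is positive when it removes heat from the body.
In a 40 degC chamber with mean skin temperature below air temperature the
convective and radiative terms are negative (dry heat gain), which inflates
the evaporative requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIGMA",
    "LAMBDA_EVAP",
    "DEFAULT_AIR_VELOCITY",
    "Anthropometry",
    "HeatBalance",
    "bsa_dubois",
    "metabolic_rate",
    "external_work",
    "saturation_vapor_pressure",
    "heat_balance",
]

#: Stefan-Boltzmann constant, W m^-2 K^-4.
SIGMA = 5.670374419e-8

#: Latent heat of sweat evaporation, J per g of water.
LAMBDA_EVAP = 2426.0

#: Default chamber air velocity, m s^-1. Air movement over a treadmill in a
#: climate chamber is dominated by the walking-induced relative wind and the
#: chamber's gentle circulation; 0.3 m s^-1 reproduces the uncompensable
#: Ereq/Emax range reported for this protocol (see docs/methods.md).
DEFAULT_AIR_VELOCITY = 0.3


def bsa_dubois(mass_kg: float, height_m: float) -> float:
    """Du Bois body surface area, m^2: 0.007184 * cm^0.725 * kg^0.425."""
    if mass_kg <= 0 or height_m <= 0:
        raise ValueError("mass and height must be positive")
    return 0.007184 * (height_m * 100.0) ** 0.725 * mass_kg**0.425


@dataclass(frozen=True)
class Anthropometry:
    """Body size of a participant; BSA derives from the Du Bois formula."""

    mass_kg: float
    height_m: float
    clothing: str = "shorts/t-shirt"

    @property
    def bsa_m2(self) -> float:
        return bsa_dubois(self.mass_kg, self.height_m)


def metabolic_rate(vo2_l_min: float, rer: float) -> float:
    """Metabolic rate (W) from oxygen uptake and respiratory exchange ratio.

    The energy equivalent of oxygen is interpolated between 19630 J/L (pure
    fat oxidation, RER 0.7) and 21130 J/L (pure carbohydrate, RER 1.0).
    RER values up to 1.3 are accepted (non-metabolic CO2 during heavy
    exercise) but clamped to 1.0 for the energy equivalent.

    Parameters
    ----------
    vo2_l_min : oxygen uptake, L/min (STPD).
    rer : respiratory exchange ratio, must lie in [0.7, 1.3].
    """
    if vo2_l_min <= 0:
        raise ValueError("vo2 must be positive")
    if not 0.7 <= rer <= 1.3:
        raise ValueError(f"RER {rer} outside physiological range [0.7, 1.3]")
    r = min(rer, 1.0)
    e_o2 = (r - 0.7) / 0.3 * 21130.0 + (1.0 - r) / 0.3 * 19630.0  # J per L O2
    return vo2_l_min * e_o2 / 60.0


def external_work(mass_kg: float, speed_kmh: float, grade_pct: float) -> float:
    """Rate of external work (W) against gravity on an inclined treadmill.

    W = m * g * v * grade, with v in m/s and the grade as a fraction.
    """
    if grade_pct < 0:
        raise ValueError("grade must be non-negative")
    return mass_kg * 9.81 * (speed_kmh / 3.6) * grade_pct / 100.0


def saturation_vapor_pressure(t_c):
    """Saturation water-vapor pressure (kPa) over water, Antoine-type form.

    p_sat = 0.61121 * exp(17.502 * T / (240.97 + T)), T in degC.
    Valid for -20 <= T <= 60 degC; accepts scalars or arrays.
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t < -20.0) or np.any(t > 60.0):
        raise ValueError("temperature outside supported range [-20, 60] degC")
    p = 0.61121 * np.exp(17.502 * t / (240.97 + t))
    return float(p) if np.isscalar(t_c) or p.ndim == 0 else p


@dataclass
class HeatBalance:
    """Component fluxes of one steady-state heat balance (all W, loss > 0)."""

    m_rate: float  # metabolic rate M
    w_ext: float  # external work
    conv: float  # convective exchange C
    rad: float  # radiative exchange R
    c_res: float  # respiratory convective exchange
    e_res: float  # respiratory evaporative exchange
    e_req: float  # evaporation required for balance
    e_max: float  # maximum environmental evaporation
    ratio: float  # Ereq / Emax, > 1 means uncompensable
    resp_mass_loss_g_s: float  # respiratory water-loss rate, g/s
    assumptions: dict = field(default_factory=dict)


def heat_balance(
    anthro: Anthropometry,
    ta_c: float,
    rh_pct: float,
    air_velocity_ms: float = DEFAULT_AIR_VELOCITY,
    tsk_c: float = 36.3,
    m_rate_w: float = 500.0,
    w_ext_w: float = 0.0,
    *,
    emissivity: float = 0.95,
    ar_ad: float = 0.70,
    t_radiant_c: float | None = None,
    hc_coef: float = 8.3,
    hc_exp: float = 0.6,
    lewis_k_per_kpa: float = 16.5,
    lambda_evap: float = LAMBDA_EVAP,
) -> HeatBalance:
    """Single steady-state partitional heat balance for one visit.

    Transfer coefficients follow the conventional forms for a walking human:
    hc = 8.3 v^0.6 (W m^-2 K^-1); the linearized radiative coefficient uses
    emissivity 0.95 and an effective radiating area fraction Ar/AD = 0.70;
    respiratory exchanges use the 0.0014/0.0173 ventilation-derived
    constants; Emax couples to convection through the Lewis relation
    (16.5 degC/kPa). The mean radiant temperature defaults to air
    temperature (climate-chamber assumption). All coefficients are
    overridable keyword arguments and are recorded in ``assumptions``.
    """
    if air_velocity_ms <= 0:
        raise ValueError("air velocity must be positive")
    if not 0 <= rh_pct <= 100:
        raise ValueError("RH must lie in [0, 100]")
    t_r = ta_c if t_radiant_c is None else t_radiant_c

    bsa = anthro.bsa_m2
    hc = hc_coef * air_velocity_ms**hc_exp
    conv = hc * bsa * (tsk_c - ta_c)
    hr = 4.0 * emissivity * SIGMA * ar_ad * ((tsk_c + t_r) / 2.0 + 273.15) ** 3
    rad = hr * bsa * (tsk_c - t_r)

    p_a = rh_pct / 100.0 * saturation_vapor_pressure(ta_c)
    c_res = 0.0014 * m_rate_w * (34.0 - ta_c)
    e_res = 0.0173 * m_rate_w * (5.87 - p_a)

    e_req = m_rate_w - w_ext_w - conv - rad - c_res - e_res
    e_max = lewis_k_per_kpa * hc * bsa * (saturation_vapor_pressure(tsk_c) - p_a)
    if e_max <= 0:
        raise ValueError("no evaporative gradient: Psat(Tsk) <= ambient vapor pressure")

    return HeatBalance(
        m_rate=m_rate_w,
        w_ext=w_ext_w,
        conv=conv,
        rad=rad,
        c_res=c_res,
        e_res=e_res,
        e_req=e_req,
        e_max=e_max,
        ratio=e_req / e_max,
        resp_mass_loss_g_s=e_res / lambda_evap,
        assumptions={
            "air_velocity_ms": air_velocity_ms,
            "emissivity": emissivity,
            "ar_ad": ar_ad,
            "t_radiant_c": t_r,
            "hc_coef": hc_coef,
            "hc_exp": hc_exp,
            "lewis_k_per_kpa": lewis_k_per_kpa,
            "lambda_evap": lambda_evap,
        },
    )
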