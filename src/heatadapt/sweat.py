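"""Sudomotor analysis: local sweat rate, sweating onset, whole-body sweat loss.

Local sweat rate (LSR) comes from ventilated-capsule hygrometry: anhydrous
air is drawn over a sealed patch of skin and the water-vapor content of the
effluent stream gives the evaporation rate per unit area. The onset of
sweating and the thermosensitivity (post-onset slope) are estimated with a
two-segment "flat then linear" least-squares model whose breakpoint is found
by exhaustive search over the observed sample times. Whole-body sweat loss
(WBSL) is a pre/post mass balance corrected for sweat trapped in clothing
and for respiratory water loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calorimetry import LAMBDA_EVAP, saturation_vapor_pressure

__all__ = [
    "CapsuleConfig",
    "SegmentedFit",
    "MassBalance",
    "vapor_density",
    "lsr_from_hygrometry",
    "fit_segmented",
    "onset_tgi",
    "respiratory_water_loss",
    "wbsl",
]

#: Specific gas constant of water vapor, J kg^-1 K^-1.
R_WATER_VAPOR = 461.52


@dataclass(frozen=True)
class CapsuleConfig:
    """Geometry and flow of one ventilated sweat capsule."""

    area_cm2: float = 4.0
    flow_ml_min: float = 500.0
    sample_hz: float = 0.2
    site: str = "back"

    def __post_init__(self):
        if self.area_cm2 <= 0 or self.flow_ml_min <= 0:
            raise ValueError("capsule area and flow must be positive")


def vapor_density(rh_pct, temp_c):
    """Water-vapor density of moist air, g m^-3 (ideal-gas conversion)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("RH must lie in [0, 100] %")
    p_kpa = rh / 100.0 * saturation_vapor_pressure(temp_c)
    t_k = np.asarray(temp_c, dtype=float) + 273.15
    rho = p_kpa * 1000.0 / (R_WATER_VAPOR * t_k) * 1000.0  # g/m3
    return float(rho) if rho.ndim == 0 else rho


def lsr_from_hygrometry(rh_pct, temp_c, config: CapsuleConfig = CapsuleConfig()):
    """Local sweat rate, mg cm^-2 min^-1, from effluent humidity and temperature.

    LSR = vapor density of the effluent (the inlet air is anhydrous) times
    the volumetric flow, divided by the capsule area. 1 g m^-3 == 1 mg L^-1,
    so with flow in L/min the product is already in mg/min.
    """
    rho_mg_l = vapor_density(rh_pct, temp_c)  # g/m3 == mg/L
    flow_l_min = config.flow_ml_min / 1000.0
    return rho_mg_l * flow_l_min / config.area_cm2


def effluent_rh_for_lsr(lsr_mg_cm2_min, temp_c, config: CapsuleConfig = CapsuleConfig()):
    """Inverse of :func:`lsr_from_hygrometry`: effluent RH that yields a given LSR."""
    lsr = np.asarray(lsr_mg_cm2_min, dtype=float)
    rho_sat = vapor_density(100.0, temp_c)
    flow_l_min = config.flow_ml_min / 1000.0
    rh = lsr * config.area_cm2 / (flow_l_min * rho_sat) * 100.0
    if np.any(rh > 100.0):
        raise ValueError("requested LSR exceeds saturation of the effluent stream")
    return float(rh) if rh.ndim == 0 else rh


@dataclass
class SegmentedFit:
    """Flat-then-linear sweat-onset model: LSR = a for t <= t0, a + b (t - t0) after."""

    t0_min: float
    baseline: float  # a, mg cm^-2 min^-1
    slope: float  # b (thermosensitivity), mg cm^-2 min^-1 per min
    sse: float
    converged: bool
    p_value: float
    slope_negative: bool = False
    onset_tgi_c: float | None = None


def _segment_sse(t: np.ndarray, y: np.ndarray, t0: float):
    """Closed-form least squares of the two-segment model at a fixed breakpoint."""
    x = np.maximum(0.0, t - t0)
    n = t.size
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    det = n * sxx - sx * sx
    if det <= 1e-12 * max(n * sxx, 1.0):  # breakpoint at/after last point: flat model
        a, b = sy / n, 0.0
    else:
        b = (n * sxy - sx * sy) / det
        a = (sy - b * sx) / n
    r = y - (a + b * x)
    return a, b, float(r @ r)


def fit_segmented(time_min, lsr, *, alpha: float = 0.05) -> SegmentedFit:
    """Estimate sweating onset and thermosensitivity by breakpoint grid search.

    The breakpoint candidates are the observed sample times (interior points
    only, so both segments are identified); for each candidate the intercept
    and slope have closed-form least-squares solutions, and the global SSE
    minimizer is returned, ties broken toward the earliest breakpoint. If an
    F-test of the segmented model against a flat line is not significant at
    ``alpha`` the trace is declared onset-free (``converged=False``).
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(lsr, dtype=float)
    if t.size != y.size:
        raise ValueError("time and LSR must have equal length")
    if t.size < 10:
        raise ValueError("need at least 10 samples to fit a breakpoint")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    candidates = t[1:-2]  # keep >= 2 points on the rising segment
    best = None
    for t0 in candidates:
        a, b, sse = _segment_sse(t, y, t0)
        if best is None or sse < best[3] - 1e-12 * (1 + best[3]):
            best = (t0, a, b, sse)
    t0, a, b, sse = best

    ybar = y.mean()
    sse_flat = float((y - ybar) @ (y - ybar))
    n = t.size
    if sse <= 0:
        p = 0.0 if sse_flat > 0 else 1.0
    else:
        f = max(0.0, (sse_flat - sse) / 2.0) / (sse / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
    converged = p < alpha and b != 0.0
    return SegmentedFit(
        t0_min=float(t0),
        baseline=float(a),
        slope=float(b),
        sse=sse,
        converged=converged,
        p_value=p,
        slope_negative=b < 0,
    )


def onset_tgi(fit: SegmentedFit, tgi_time_min, tgi_c) -> float:
    """Core temperature at the sweating onset: interpolate Tgi at the breakpoint."""
    if not fit.converged:
        raise ValueError("segmented fit did not identify an onset")
    t = np.asarray(tgi_time_min, dtype=float)
    y = np.asarray(tgi_c, dtype=float)
    if not t[0] <= fit.t0_min <= t[-1]:
        raise ValueError("breakpoint outside the support of the Tgi trace")
    return float(np.interp(fit.t0_min, t, y))


@dataclass
class MassBalance:
    """Pre/post mass accounting of one exercise bout (kg; 1 kg water == 1 L)."""

    pre_clothed_kg: float
    post_clothed_kg: float
    pre_clothing_kg: float
    post_clothing_kg: float
    fluid_intake_kg: float
    resp_water_kg: float
    duration_min: float
    wbsl_l: float
    negative_flagged: bool = False


def respiratory_water_loss(e_res_w: float, duration_min: float, lambda_evap: float = LAMBDA_EVAP) -> float:
    """Respiratory water loss (kg) over a bout from the respiratory evaporative flux."""
    return e_res_w / lambda_evap * duration_min * 60.0 / 1000.0


def wbsl(
    pre_clothed_kg: float,
    post_clothed_kg: float,
    pre_clothing_kg: float,
    post_clothing_kg: float,
    *,
    fluid_intake_kg: float = 0.0,
    resp_water_kg: float = 0.0,
    duration_min: float = 45.0,
) -> MassBalance:
    """Whole-body sweat loss from the clothed/clothing mass balance.

    Nude mass change = (pre clothed - pre clothing) - (post clothed - post
    clothing); sweat trapped in clothing therefore counts toward WBSL, since
    a clothing-mass gain at constant clothed mass appears as a nude-mass
    loss. WBSL = nude change + fluid intake - respiratory water loss.
    A negative result is returned but flagged rather than raised.
    """
    for m in (pre_clothed_kg, post_clothed_kg, pre_clothing_kg, post_clothing_kg):
        if m <= 0:
            raise ValueError("all masses must be positive")
    if post_clothing_kg < pre_clothing_kg - 1e-9:
        raise ValueError("clothing cannot lose mass during the bout (trapped sweat only)")
    nude_change = (pre_clothed_kg - pre_clothing_kg) - (post_clothed_kg - post_clothing_kg)
    total = nude_change + fluid_intake_kg - resp_water_kg
    return MassBalance(
        pre_clothed_kg=pre_clothed_kg,
        post_clothed_kg=post_clothed_kg,
        pre_clothing_kg=pre_clothing_kg,
        post_clothing_kg=post_clothing_kg,
        fluid_intake_kg=fluid_intake_kg,
        resp_water_kg=resp_water_kg,
        duration_min=duration_min,
        wbsl_l=total,
        negative_flagged=total < 0,
    )
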