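"""Synthetic cohorts and signals with known ground truth.

The study design this package targets — fifteen active adolescents (five
female) measured before and after an austral summer, each completing a
45-min heat response test in 40 degC / 30% RH — is reproduced here as a set
of fully seeded generators: participant rosters with known pre/post effect
structure, heat-response-test time series built from deterministic
templates plus noise, CO-rebreathing records that are exact inverses of the
hematology calculations, an hourly meteorological half-year for a
mid-latitude southern-hemisphere site, and activity diaries with matched
accelerometer epochs. Every generator is deterministic under a fixed seed,
and each noiseless forward model is inverted exactly by the corresponding
analysis operation, so the whole downstream chain is testable without any
participant data.

Default parameter values are the study conditions: cohort anthropometry,
outcome baselines, pre/post shifts and dispersions follow the printed
pre/post summaries; the meteorological defaults emulate a Canberra-like
temperate summer; the activity defaults place 49% of outdoor bouts between
15:00 and 18:00 and 28% between 05:00 and 08:00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hematology import F_CELL, HUFNER_ML_CO_PER_G, MCHC_G_DL, RebreatheRecord
from .sweat import CapsuleConfig, effluent_rh_for_lsr
from .thermometry import HRTSeries

__all__ = [
    "OUTCOME_DEFAULTS",
    "CohortConfig",
    "HRTGroundTruth",
    "MetParams",
    "generate_cohort",
    "simulate_outcome_table",
    "generate_hrt_series",
    "generate_met_year",
    "generate_co_rebreathe",
    "generate_activity_week",
]

#: Per-outcome study conditions: (pre-summer baseline, pre->post shift,
#: between-participant SD, within-participant residual SD), in the outcome's
#: printed units.
OUTCOME_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "resting_tgi": (37.28, -0.19, 0.20, 0.12),
    "resting_hr": (80.0, -7.0, 8.0, 4.0),
    "resting_tsk": (32.15, -0.02, 0.60, 0.40),
    "rise_tgi": (1.78, -0.22, 0.35, 0.25),
    "end_tgi": (38.95, -0.35, 0.40, 0.25),
    "mean_tsk_exercise": (36.3, -0.2, 0.35, 0.30),
    "onset_tgi": (37.2, -0.15, 0.15, 0.08),
    "sweat_sensitivity": (0.10, -0.01, 0.030, 0.010),
    "wbsl": (0.78, 0.03, 0.18, 0.10),
    "hb_mass_g_kg": (11.6, 0.3, 1.2, 0.6),
    "plasma_volume_ml_kg": (47.5, -0.5, 4.0, 2.5),
    "blood_volume_ml_kg": (78.8, -1.1, 6.5, 4.0),
    "vo2peak": (60.4, 1.2, 7.5, 2.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating parameters (defaults are the study conditions)."""

    n_participants: int = 15
    n_female: int = 5
    seed: int = 0
    mass_mean_kg: float = 56.84
    mass_sd_kg: float = 9.05
    height_mean_m: float = 1.70
    height_sd_m: float = 0.08
    vo2peak_mean: float = 60.4
    vo2peak_sd: float = 7.5
    true_effects: dict = field(default_factory=lambda: {k: v[1] for k, v in OUTCOME_DEFAULTS.items()})
    baselines: dict = field(default_factory=lambda: {k: v[0] for k, v in OUTCOME_DEFAULTS.items()})
    between_participant_sd: dict = field(default_factory=lambda: {k: v[2] for k, v in OUTCOME_DEFAULTS.items()})
    within_participant_sd: dict = field(default_factory=lambda: {k: v[3] for k, v in OUTCOME_DEFAULTS.items()})

    def __post_init__(self):
        if self.n_participants < 1 or not 0 <= self.n_female <= self.n_participants:
            raise ValueError("need 0 <= n_female <= n_participants, n_participants >= 1")
        for d in (self.between_participant_sd, self.within_participant_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("dispersions must be non-negative")
        if self.mass_sd_kg < 0 or self.height_sd_m < 0 or self.vo2peak_sd < 0:
            raise ValueError("dispersions must be non-negative")


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Roster of participants with true (noise-free) per-outcome pre/post values.

    Each outcome's true pre value is baseline + participant intercept
    (Normal(0, between-participant SD)); the true post value adds the
    configured period shift. Measurement noise is applied later by
    :func:`simulate_outcome_table`, so with zero between-participant SD every
    participant's post - pre difference equals the shift exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    rows = {
        "participant": [f"P{i + 1:02d}" for i in range(n)],
        "sex": ["F"] * config.n_female + ["M"] * (n - config.n_female),
        "mass_kg": np.clip(rng.normal(config.mass_mean_kg, config.mass_sd_kg, n), 30.0, None),
        "height_m": np.clip(rng.normal(config.height_mean_m, config.height_sd_m, n), 1.3, None),
        "vo2peak": np.clip(rng.normal(config.vo2peak_mean, config.vo2peak_sd, n), 25.0, None),
    }
    for name, baseline in config.baselines.items():
        u = rng.normal(0.0, config.between_participant_sd.get(name, 0.0), n)
        shift = config.true_effects.get(name, 0.0)
        rows[f"pre_{name}"] = baseline + u
        rows[f"post_{name}"] = baseline + u + shift
    return pd.DataFrame(rows)


def simulate_outcome_table(
    roster: pd.DataFrame, outcome: str, within_sd: float, seed: int
) -> pd.DataFrame:
    """Observed pre/post measurements of one outcome in tidy long form.

    Adds Normal(0, within_sd) measurement noise to the roster's true values;
    output columns are (participant, period, value, vo2peak), one row per
    participant-period, ready for the hierarchical model.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for _, r in roster.iterrows():
        for period in ("pre", "post"):
            recs.append(
                {
                    "participant": r["participant"],
                    "period": period,
                    "value": r[f"{period}_{outcome}"] + rng.normal(0.0, within_sd),
                    "vo2peak": r["vo2peak"],
                }
            )
    return pd.DataFrame(recs)


@dataclass(frozen=True)
class HRTGroundTruth:
    """Deterministic template parameters of one heat-response-test visit.

    The core-temperature template rises logistically from the baseline
    toward baseline + rise_total (monotone, plateauing); the local-sweat-
    rate template is flat at the baseline until ``onset_time_min`` and then
    rises linearly at ``sweat_sensitivity`` until capped at the plateau.
    ``onset_tgi`` is the template core temperature at the sweating onset.
    """

    tgi_baseline_c: float = 37.28
    tgi_rise_total_c: float = 1.78
    tsk_rest_c: float = 32.15
    tsk_plateau_c: float = 36.3
    hr_baseline: float = 80.0
    hr_rise: float = 97.0
    onset_time_min: float = 10.0
    lsr_baseline: float = 0.05
    sweat_sensitivity: float = 0.09  # mg cm^-2 min^-1 per min
    lsr_plateau: float = 1.36
    effluent_temp_c: float = 35.0
    noise_sd: dict = field(
        default_factory=lambda: {"tgi": 0.04, "tsk": 0.10, "hr": 2.0, "lsr": 0.03}
    )

    def __post_init__(self):
        if not 0.0 < self.onset_time_min < 45.0:
            raise ValueError("sweating onset must lie inside (0, 45) min")
        if self.sweat_sensitivity < 0:
            raise ValueError("sweat sensitivity must be non-negative")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")

    # --- deterministic templates -------------------------------------------------

    def tgi_template(self, t_min):
        """Logistic-saturating core-temperature rise, degC; flat during rest."""
        t = np.asarray(t_min, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(t - 15.0) / 6.0))
        s0 = 1.0 / (1.0 + math.exp(15.0 / 6.0))
        s45 = 1.0 / (1.0 + math.exp(-30.0 / 6.0))
        out = self.tgi_baseline_c + self.tgi_rise_total_c * (s - s0) / (s45 - s0)
        out = np.where(t < 0, self.tgi_baseline_c, out)
        return float(out) if out.ndim == 0 else out

    def tsk_template(self, t_min):
        t = np.asarray(t_min, dtype=float)
        rise = self.tsk_plateau_c - self.tsk_rest_c
        out = np.where(t < 0, self.tsk_rest_c, self.tsk_rest_c + rise * (1 - np.exp(-t / 6.0)))
        return float(out) if out.ndim == 0 else out

    def hr_template(self, t_min):
        t = np.asarray(t_min, dtype=float)
        norm = 1 - math.exp(-45.0 / 10.0)
        out = np.where(
            t < 0, self.hr_baseline, self.hr_baseline + self.hr_rise * (1 - np.exp(-t / 10.0)) / norm
        )
        return float(out) if out.ndim == 0 else out

    def lsr_template(self, t_min):
        """Flat baseline, then linear rise at the sensitivity, capped at the plateau."""
        t = np.asarray(t_min, dtype=float)
        lin = self.lsr_baseline + self.sweat_sensitivity * np.maximum(0.0, t - self.onset_time_min)
        out = np.minimum(lin, self.lsr_plateau)
        return float(out) if out.ndim == 0 else out

    @property
    def onset_tgi_c(self) -> float:
        return float(self.tgi_template(self.onset_time_min))


def generate_hrt_series(
    truth: HRTGroundTruth,
    seed: int,
    *,
    participant: str = "P01",
    period: str = "pre",
    capsule: CapsuleConfig = CapsuleConfig(),
) -> HRTSeries:
    """One noisy heat-response-test visit on the native sampling grids.

    Tgi every 15 s and skin every 1 min from 10 min of rest through 45 min
    of exercise; heart rate every 5 min; capsule hygrometry every 5 s during
    exercise for both the back and forearm sites. One random stream is
    spawned per signal from the visit seed, so adding or dropping a signal
    never perturbs the others. Capsule noise is injected on the sweat-rate
    scale and converted exactly to effluent humidity, so the hygrometry
    analysis recovers the noisy LSR without approximation.
    """
    streams = np.random.SeedSequence(seed).spawn(6)
    r_tgi, r_tsk, r_hr, r_back, r_fore, _ = [np.random.default_rng(s) for s in streams]

    t_tgi = np.arange(-10.0, 45.0 + 1e-9, 0.25)
    tgi = truth.tgi_template(t_tgi) + r_tgi.normal(0.0, truth.noise_sd["tgi"], t_tgi.size)

    t_tsk = np.arange(-10.0, 45.0 + 1e-9, 1.0)
    base_tsk = truth.tsk_template(t_tsk)
    offsets = {"chest": 0.4, "shoulder": 0.2, "thigh": -0.3, "calf": -0.6}
    tsk = {
        site: np.clip(base_tsk + off + r_tsk.normal(0.0, truth.noise_sd["tsk"], t_tsk.size), 10.5, 44.5)
        for site, off in offsets.items()
    }

    t_hr = np.arange(-10.0, 45.0 + 1e-9, 5.0)
    hr = np.clip(
        truth.hr_template(t_hr) + r_hr.normal(0.0, truth.noise_sd["hr"], t_hr.size), 40.0, 220.0
    )

    t_cap = np.arange(0.0, 45.0 + 1e-9, 1.0 / (capsule.sample_hz * 60.0))
    capsules = {}
    for site, r in (("back", r_back), ("forearm", r_fore)):
        lsr = np.clip(
            truth.lsr_template(t_cap) + r.normal(0.0, truth.noise_sd["lsr"], t_cap.size), 0.0, None
        )
        rh = effluent_rh_for_lsr(lsr, truth.effluent_temp_c, replace(capsule, site=site))
        capsules[site] = (
            t_cap,
            rh,
            np.full(t_cap.size, truth.effluent_temp_c),
        )

    return HRTSeries(
        participant=participant,
        period=period,
        tgi_time_min=t_tgi,
        tgi_c=np.clip(tgi, 35.0, 41.0),
        tsk_time_min=t_tsk,
        tsk_c=tsk,
        hr_time_min=t_hr,
        hr_bpm=hr,
        capsules=capsules,
    )


@dataclass(frozen=True)
class MetParams:
    """Sinusoidal seasonal/diurnal weather model for a temperate site.

    Defaults emulate a Canberra-like summer: annual mean ~12.5 degC with a
    7 degC seasonal amplitude peaking in mid-January (southern hemisphere),
    a 5.5 degC diurnal amplitude peaking at 15:00, AR(1) hourly noise,
    humidity anti-correlated with the diurnal temperature anomaly, gamma
    winds and beta-distributed daily cloud fraction.
    """

    t_mean_c: float = 12.5
    seasonal_amp_c: float = 7.0
    peak_doy: float = 20.0  # day of year of the seasonal maximum
    diurnal_amp_c: float = 5.5
    diurnal_peak_hour: float = 15.0
    noise_sd_c: float = 1.5
    ar1: float = 0.7
    rh_base_pct: float = 68.0
    rh_anomaly_slope: float = -4.5  # % RH per degC of diurnal+noise anomaly
    rh_noise_sd: float = 8.0
    wind_mean_ms: float = 2.0
    cloud_beta_a: float = 1.2
    cloud_beta_b: float = 1.8


def generate_met_year(
    lat: float = -35.31,
    lon: float = 149.13,
    start_date: str = "2022-10-01",
    n_days: int = 182,
    seed: int = 0,
    params: MetParams = MetParams(),
) -> pd.DataFrame:
    """Hourly meteorological table (24 * n_days rows) with known structure.

    Columns: timestamp (local standard time, ISO-8601 under to_csv),
    dry_bulb_c, rh_pct, wind_ms, cloud_frac, lat, lon.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start_date, periods=24 * n_days, freq="h")
    doy = ts.dayofyear.to_numpy()
    hour = ts.hour.to_numpy()

    seasonal = params.seasonal_amp_c * np.cos(2 * np.pi * (doy - params.peak_doy) / 365.25)
    diurnal = params.diurnal_amp_c * np.cos(2 * np.pi * (hour - params.diurnal_peak_hour) / 24.0)
    noise = np.empty(ts.size)
    innov_sd = params.noise_sd_c * math.sqrt(max(1e-12, 1 - params.ar1**2))
    e = rng.normal(0.0, 1.0, ts.size)
    noise[0] = params.noise_sd_c * e[0]
    for i in range(1, ts.size):
        noise[i] = params.ar1 * noise[i - 1] + innov_sd * e[i]
    dry_bulb = params.t_mean_c + seasonal + diurnal + noise

    anomaly = diurnal + noise
    rh = np.clip(
        params.rh_base_pct
        + params.rh_anomaly_slope * anomaly
        + rng.normal(0.0, params.rh_noise_sd, ts.size),
        5.0,
        100.0,
    )
    wind = rng.gamma(2.0, params.wind_mean_ms / 2.0, ts.size)
    daily_cloud = rng.beta(params.cloud_beta_a, params.cloud_beta_b, n_days)
    cloud = np.clip(
        np.repeat(daily_cloud, 24) + rng.normal(0.0, 0.05, ts.size), 0.0, 1.0
    )
    return pd.DataFrame(
        {
            "timestamp": ts,
            "dry_bulb_c": dry_bulb,
            "rh_pct": rh,
            "wind_ms": wind,
            "cloud_frac": cloud,
            "lat": lat,
            "lon": lon,
        }
    )


def generate_co_rebreathe(
    hb_mass_true_g: float,
    blood_volume_true_ml: float,
    body_mass_kg: float,
    seed: int | None = None,
    *,
    hbco_pre_pct: float = 1.0,
    unabsorbed_frac: float = 0.03,
    noise_cv_pct: float = 0.0,
) -> RebreatheRecord:
    """Forward CO-rebreathing model; exact inverse of the hematology analysis.

    The administered dose is 0.8 mL CO per kg body mass; a small fraction is
    exhaled unabsorbed. The HbCO rise follows from the Hufner capacity, the
    hemoglobin concentration from the true blood volume, and the hematocrit
    from the red-cell volume implied by an MCHC of 33 g/dL with the 0.91
    f-cell factor. With ``noise_cv_pct`` > 0 the measured HbCO rise is
    perturbed multiplicatively, which propagates one-to-one into the
    recovered hemoglobin mass (so the configured CV is the typical error).
    """
    if hb_mass_true_g <= 0 or blood_volume_true_ml <= 0 or body_mass_kg <= 0:
        raise ValueError("physiological inputs must be positive")
    co_admin = 0.8 * body_mass_kg
    co_unabs = unabsorbed_frac * co_admin
    delta = (co_admin - co_unabs) * 100.0 / (HUFNER_ML_CO_PER_G * hb_mass_true_g)
    if noise_cv_pct > 0:
        rng = np.random.default_rng(seed)
        delta /= 1.0 + rng.normal(0.0, noise_cv_pct / 100.0)
    hb_conc = hb_mass_true_g / blood_volume_true_ml * 100.0  # g/dL
    rcv = hb_mass_true_g / MCHC_G_DL * 100.0  # mL of red cells
    hct = rcv / (blood_volume_true_ml * F_CELL)
    return RebreatheRecord(
        hbco_pre_pct=hbco_pre_pct,
        hbco_post_pct=hbco_pre_pct + delta,
        hct=hct,
        co_admin_ml=co_admin,
        co_unabsorbed_ml=co_unabs,
        body_mass_kg=body_mass_kg,
        hb_conc_g_dl=hb_conc,
    )


#: Default distribution of outdoor bout start times over 3-h bins (bin start
#: hour -> probability); the 15:00-18:00 bin carries 49% and 05:00-08:00
#: carries 28% of outdoor activity.
BOUT_TIME_BINS = {5: 0.28, 8: 0.06, 11: 0.07, 15: 0.49, 18: 0.10}

_INTENSITY_RPE = {"light": (1, 3), "moderate": (4, 6), "high": (7, 10)}
_INTENSITY_COUNTS = {"light": 1800.0, "moderate": 3500.0, "high": 6000.0}


def generate_activity_week(
    hours_outdoor_per_wk: float = 7.0,
    intensity_mix: dict | None = None,
    seed: int = 0,
    *,
    start_date: str = "2022-11-07",
    hours_indoor_per_wk: float = 5.4,
    background_active_min_per_day: float = 90.0,
    time_bin_probs: dict | None = None,
):
    """One week of activity: a self-report diary plus 60-s accelerometer epochs.

    Returns ``(diary, epochs)``. The diary holds one outdoor bout per day
    (durations jittered around hours/7) plus indoor bouts, each with a start
    time drawn from the configured time-of-day bins, a location and a 0-10
    RPE consistent with its intensity category. The epoch table covers
    7 * 1440 minutes of triaxial counts: zeros overnight (non-wear), light
    background counts while awake, a block of moderate-to-vigorous
    background activity each day, and elevated counts during diary bouts.
    """
    if hours_outdoor_per_wk < 0 or hours_indoor_per_wk < 0:
        raise ValueError("weekly hours must be non-negative")
    mix = intensity_mix or {"light": 0.25, "moderate": 0.30, "high": 0.45}
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("intensity mix must sum to 1")
    probs = time_bin_probs or BOUT_TIME_BINS
    rng = np.random.default_rng(seed)
    days = pd.date_range(start_date, periods=7, freq="D")

    diary_rows = []

    def _add_bouts(total_h, location):
        if total_h <= 0:
            return
        weights = rng.dirichlet(np.full(7, 12.0))
        durations = weights * total_h
        bins = list(probs)
        p = np.array([probs[b] for b in bins], dtype=float)
        p /= p.sum()
        for day, dur in zip(days, durations):
            if dur <= 0.02:
                continue
            b = bins[rng.choice(len(bins), p=p)]
            start_h = b + rng.uniform(0.0, max(0.1, 3.0 - dur))
            intensity = rng.choice(list(mix), p=np.array(list(mix.values())))
            lo, hi = _INTENSITY_RPE[intensity]
            diary_rows.append(
                {
                    "start": day + pd.Timedelta(hours=float(start_h)),
                    "duration_h": float(dur),
                    "location": location,
                    "intensity": intensity,
                    "rpe": int(rng.integers(lo, hi + 1)),
                }
            )

    _add_bouts(hours_outdoor_per_wk, "outdoor")
    _add_bouts(hours_indoor_per_wk, "indoor")
    diary = pd.DataFrame(
        diary_rows, columns=["start", "duration_h", "location", "intensity", "rpe"]
    ).sort_values("start", ignore_index=True)

    ts = pd.date_range(start_date, periods=7 * 1440, freq="min")
    hour = ts.hour.to_numpy()
    vm = np.zeros(ts.size)
    awake = (hour >= 7) & (hour < 22)
    vm[awake] = rng.uniform(50.0, 400.0, int(awake.sum()))  # light ambulatory background

    day_index = ((ts - ts[0]).total_seconds() // 86400).astype(int)
    for d in range(7):
        n_bg = int(round(background_active_min_per_day))
        if n_bg <= 0:
            continue
        day_mask = (day_index == d) & awake
        idx = np.flatnonzero(day_mask)
        if idx.size == 0:
            continue
        pick = rng.choice(idx, size=min(n_bg, idx.size), replace=False)
        vm[pick] = rng.normal(3200.0, 350.0, pick.size)

    for _, bout in diary.iterrows():
        i0 = int((bout["start"] - ts[0]).total_seconds() // 60)
        n = max(1, int(round(bout["duration_h"] * 60.0)))
        level = _INTENSITY_COUNTS[bout["intensity"]]
        sl = slice(max(0, i0), min(ts.size, i0 + n))
        vm[sl] = rng.normal(level, 0.08 * level, sl.stop - sl.start)

    vm = np.clip(vm, 0.0, None)
    axis = vm / math.sqrt(3.0)
    epochs = pd.DataFrame(
        {
            "timestamp": ts,
            "axis1": np.round(axis).astype(int),
            "axis2": np.round(axis).astype(int),
            "axis3": np.round(axis).astype(int),
        }
    )
    return diary, epochs
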