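"""Core/skin temperature and heart-rate processing for heat response tests.

A heat response test (HRT) is a standardized 45-min uncompensable walk in
the heat preceded by a 10-min seated rest. Gastro-intestinal temperature
(Tgi) is telemetered every 15 s by an ingestible capsule, four-site skin
temperature every minute, heart rate every 5 min. This module cleans the
capsule telemetry, computes the 30/30/20/20 weighted mean skin temperature
(chest/shoulder/thigh/calf), applies the 39.5 degC safety cutoff, and
reduces a visit to its scalar summaries (resting values, rise in Tgi,
end-exercise values, exercising means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TSK_WEIGHTS",
    "UnusableTraceError",
    "HRTSeries",
    "VisitSummary",
    "mean_skin_temp",
    "clean_core_trace",
    "safety_flag",
    "summarize_visit",
    "write_hrt_csv",
    "read_hrt_csv",
]

#: Four-site weighting for mean skin temperature.
TSK_WEIGHTS = {"chest": 0.30, "shoulder": 0.30, "thigh": 0.20, "calf": 0.20}


class UnusableTraceError(ValueError):
    """Raised when telemetry QC removes too large a fraction of a trace."""


def mean_skin_temp(chest_c, shoulder_c, thigh_c, calf_c):
    """Weighted mean skin temperature: 0.3 chest + 0.3 shoulder + 0.2 thigh + 0.2 calf.

    Every site must be present and within 10-45 degC; there is no silent
    re-weighting around a missing sensor.
    """
    sites = {"chest": chest_c, "shoulder": shoulder_c, "thigh": thigh_c, "calf": calf_c}
    arrs = {}
    for name, v in sites.items():
        if v is None:
            raise ValueError(f"missing {name} skin temperature")
        a = np.asarray(v, dtype=float)
        if np.any(~np.isfinite(a)) or np.any(a < 10.0) or np.any(a > 45.0):
            raise ValueError(f"{name} skin temperature outside 10-45 degC or missing")
        arrs[name] = a
    out = sum(TSK_WEIGHTS[k] * arrs[k] for k in TSK_WEIGHTS)
    return float(out) if np.ndim(out) == 0 else out


def clean_core_trace(
    time_min,
    tgi_c,
    *,
    lower_c: float = 30.0,
    upper_c: float = 43.0,
    max_jump_c: float = 0.5,
    max_removed_frac: float = 0.2,
):
    """QC a capsule Tgi trace: drop impossible points, interpolate across them.

    A sample is rejected when it falls outside [30, 43] degC or jumps more
    than ``max_jump_c`` from the last accepted sample (telemetry dropouts
    read near 0 or spike). Rejected samples are replaced by linear
    interpolation between accepted neighbours. If more than
    ``max_removed_frac`` of the trace is rejected the trace is unusable.

    Returns ``(cleaned, removed_indices)``; cleaning is idempotent on its
    own output for isolated artifacts.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(tgi_c, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    bad = ~np.isfinite(y) | (y < lower_c) | (y > upper_c)
    # jump detection relative to the last accepted sample
    last_good = None
    for i in range(t.size):
        if bad[i]:
            continue
        if last_good is not None and abs(y[i] - y[last_good]) > max_jump_c * max(1, i - last_good):
            bad[i] = True
        else:
            last_good = i
    removed = np.flatnonzero(bad)
    if removed.size > max_removed_frac * t.size:
        raise UnusableTraceError(
            f"{removed.size}/{t.size} samples rejected (> {max_removed_frac:.0%})"
        )
    cleaned = y.copy()
    if removed.size:
        good = ~bad
        if good.sum() < 2:
            raise UnusableTraceError("fewer than 2 usable samples")
        cleaned[bad] = np.interp(t[bad], t[good], y[good])
    return cleaned, removed


def safety_flag(time_min, tgi_c, cutoff_c: float = 39.5):
    """First time (min) the core temperature reaches the safety cutoff, or None."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(tgi_c, dtype=float)
    hit = np.flatnonzero(y >= cutoff_c)
    return float(t[hit[0]]) if hit.size else None


@dataclass
class HRTSeries:
    """Synchronized signals of one participant-visit.

    Times are minutes from exercise onset (negative during the pre-exercise
    rest). Each signal keeps its native cadence: Tgi every 15 s, skin sites
    every 1 min, heart rate every 5 min, capsule hygrometry every 5 s.
    """

    participant: str
    period: str  # "pre" | "post"
    tgi_time_min: np.ndarray
    tgi_c: np.ndarray
    tsk_time_min: np.ndarray
    tsk_c: dict  # site -> array, sites per TSK_WEIGHTS
    hr_time_min: np.ndarray
    hr_bpm: np.ndarray
    capsules: dict = field(default_factory=dict)  # site -> (time_min, rh_pct, temp_c)
    chamber_ta_c: float = 40.0
    chamber_rh_pct: float = 30.0

    def __post_init__(self):
        if self.period not in ("pre", "post"):
            raise ValueError("period must be 'pre' or 'post'")
        for t in (self.tgi_time_min, self.tsk_time_min, self.hr_time_min):
            if np.any(np.diff(t) <= 0):
                raise ValueError("time must be strictly increasing within each signal")

    def mean_tsk(self) -> np.ndarray:
        return mean_skin_temp(
            self.tsk_c["chest"], self.tsk_c["shoulder"], self.tsk_c["thigh"], self.tsk_c["calf"]
        )


@dataclass
class VisitSummary:
    resting_tgi_c: float
    resting_tsk_c: float
    resting_hr_bpm: float
    rise_tgi_c: float
    end_tgi_c: float
    mean_tsk_exercise_c: float
    end_hr_bpm: float
    mean_hr_exercise_bpm: float
    safety_stop: bool
    stop_time_min: float


def summarize_visit(
    series: HRTSeries,
    *,
    rest_window_min: float = 5.0,
    exercise_end_min: float = 45.0,
    cutoff_c: float = 39.5,
) -> VisitSummary:
    """Reduce one visit to its scalar summaries.

    Resting values are means over the final ``rest_window_min`` minutes of
    the pre-exercise rest (instrumentation transients earlier in the rest
    are discarded). The rise in Tgi is referenced to the exercise-onset
    sample; end values are the final exercising samples; exercising means
    run from 0 to 45 min, or to the safety-stop time when the 39.5 degC
    cutoff was reached.
    """
    tgi_t, tgi = series.tgi_time_min, series.tgi_c
    if tgi_t[0] > -rest_window_min:
        raise ValueError(f"rest window of {rest_window_min} min not present before exercise")
    ex = tgi_t >= 0
    if not np.any(ex):
        raise ValueError("no exercise window present")

    stop = safety_flag(tgi_t[ex], tgi[ex], cutoff_c)
    stop_time = min(stop, exercise_end_min) if stop is not None else exercise_end_min

    def _rest(t, y):
        m = (t >= -rest_window_min) & (t < 0)
        if not np.any(m):
            raise ValueError("rest window absent from a signal")
        return float(np.mean(y[m]))

    def _exercise(t, y):
        m = (t >= 0) & (t <= stop_time)
        return t[m], y[m]

    tex, yex = _exercise(tgi_t, tgi)
    end_tgi = float(yex[-1])
    tgi_at_onset = float(yex[0])

    tsk = series.mean_tsk()
    _, tsk_ex = _exercise(series.tsk_time_min, tsk)
    _, hr_ex = _exercise(series.hr_time_min, series.hr_bpm)

    return VisitSummary(
        resting_tgi_c=_rest(tgi_t, tgi),
        resting_tsk_c=_rest(series.tsk_time_min, tsk),
        resting_hr_bpm=_rest(series.hr_time_min, series.hr_bpm),
        rise_tgi_c=end_tgi - tgi_at_onset,
        end_tgi_c=end_tgi,
        mean_tsk_exercise_c=float(np.mean(tsk_ex)),
        end_hr_bpm=float(hr_ex[-1]),
        mean_hr_exercise_bpm=float(np.mean(hr_ex)),
        safety_stop=stop is not None,
        stop_time_min=stop_time,
    )


def write_hrt_csv(series: HRTSeries, path) -> None:
    """Write the wide per-visit CSV (t_min, tgi_c, tsk_*_c, hr_bpm; NaN off-cadence)."""
    frames = [
        pd.DataFrame({"t_min": series.tgi_time_min, "tgi_c": series.tgi_c}),
        pd.DataFrame(
            {"t_min": series.tsk_time_min}
            | {f"tsk_{k}_c": v for k, v in series.tsk_c.items()}
        ),
        pd.DataFrame({"t_min": series.hr_time_min, "hr_bpm": series.hr_bpm}),
    ]
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="t_min", how="outer")
    out.sort_values("t_min").to_csv(path, index=False)


def read_hrt_csv(path, participant: str = "", period: str = "pre", **kwargs) -> HRTSeries:
    """Read a per-visit CSV written by :func:`write_hrt_csv`."""
    df = pd.read_csv(path)

    def _channel(cols):
        sub = df[["t_min", *cols]].dropna()
        return sub["t_min"].to_numpy(), sub

    t_tgi, sub = _channel(["tgi_c"])
    tgi = sub["tgi_c"].to_numpy()
    tsk_cols = [f"tsk_{k}_c" for k in TSK_WEIGHTS]
    t_tsk, sub = _channel(tsk_cols)
    tsk = {k: sub[f"tsk_{k}_c"].to_numpy() for k in TSK_WEIGHTS}
    t_hr, sub = _channel(["hr_bpm"])
    hr = sub["hr_bpm"].to_numpy()
    return HRTSeries(
        participant=participant,
        period=period,
        tgi_time_min=t_tgi,
        tgi_c=tgi,
        tsk_time_min=t_tsk,
        tsk_c=tsk,
        hr_time_min=t_hr,
        hr_bpm=hr,
        **kwargs,
    )
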