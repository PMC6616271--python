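"""Weather processing: VPD, daily reference evapotranspiration and stage aggregates.

Implements the standard FAO-56 formulation: Tetens saturation vapour pressure,
the daily Penman-Monteith reference-evapotranspiration (ET0) equation with net
radiation derived from measured solar radiation, and the dual-coefficient crop
evapotranspiration ETc = (Kcb + Ke) * ET0 with Kcb = 1.05 * EAS (effective area
of shade).  Stage aggregates mirror the seasonal summary used in deficit
irrigation trials: per fruit-growth stage, the sum of average daily VPD
(sigma_VPD), cumulative daily ET0 (sigma_ET0) and their per-day means
(mu_VPD, mu_ET0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Stefan-Boltzmann constant in MJ K-4 m-2 day-1 (FAO-56 daily form).
STEFAN_BOLTZMANN = 4.903e-9

#: Reference-surface albedo for grass (dimensionless).
ALBEDO = 0.23

#: Solar constant, MJ m-2 min-1.
SOLAR_CONSTANT = 0.0820

WEATHER_COLUMNS = ("temp_c", "rh_pct", "solar_wm2", "wind_ms", "rain_mm")


# ---------------------------------------------------------------------------
# Site and crop metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMetadata:
    """Location metadata needed by the daily ET0 computation.

    Parameters
    ----------
    latitude_deg : float
        Site latitude in decimal degrees (negative in the southern hemisphere).
    elevation_m : float
        Elevation above sea level in metres; sets the psychrometric constant.
    anemometer_height_m : float
        Height of the wind measurement; wind is normalised to 2 m.
    """

    latitude_deg: float
    elevation_m: float
    anemometer_height_m: float = 2.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValidationError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if self.anemometer_height_m <= 0:
            raise ValidationError("anemometer height must be positive")


@dataclass(frozen=True)
class CropCoefficients:
    """Dual crop coefficients: Kcb = 1.05 * EAS plus a soil evaporation term Ke."""

    eas: float = 0.30
    ke: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.eas <= 1.0:
            raise ValidationError(f"EAS {self.eas} outside [0, 1]")
        if self.ke < 0:
            raise ValidationError(f"Ke {self.ke} must be >= 0")

    @property
    def kcb(self) -> float:
        return 1.05 * self.eas


@dataclass(frozen=True)
class StageDefinition:
    """A fruit-growth stage as a closed DAFB (days after full bloom) interval."""

    stage_id: str
    start_dafb: int
    end_dafb: int

    def __post_init__(self) -> None:
        if self.end_dafb < self.start_dafb:
            raise ValidationError(f"stage {self.stage_id}: end before start")

    @property
    def duration_days(self) -> int:
        return self.end_dafb - self.start_dafb + 1


@dataclass
class StageSummary:
    """Per-stage weather aggregates (the seasonal summary-table analogue)."""

    stage_id: str
    duration_days: int
    days_with_data: int
    rainfall_total: float
    vpd_mean_daily: float
    vpd_cumulative: float
    et0_mean_daily: float
    et0_cumulative: float
    etc_cumulative: float | None = None
    irrigation_by_treatment: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core scalar relations
# ---------------------------------------------------------------------------


def saturation_vapor_pressure(temp_c):
    """Tetens saturation vapour pressure es(T) in kPa.

    es(T) = 0.6108 * exp(17.27 T / (T + 237.3)), T in deg C.
    """
    t = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def slope_vapor_pressure_curve(temp_c):
    """Slope of the saturation vapour pressure curve, kPa per deg C."""
    t = np.asarray(temp_c, dtype=float)
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def compute_vpd(temp_c, rh_pct):
    """Vapour pressure deficit in kPa from air temperature and relative humidity.

    VPD = es(T) * (1 - RH/100).  Zero exactly at saturation, strictly
    increasing in T and strictly decreasing in RH.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((t < -40.0) | (t > 60.0)):
        bad = np.argwhere((t < -40.0) | (t > 60.0)).ravel()[:5]
        raise ValidationError(f"air temperature outside [-40, 60] degC at records {bad.tolist()}")
    if np.any((rh < 0.0) | (rh > 100.0)):
        bad = np.argwhere((rh < 0.0) | (rh > 100.0)).ravel()[:5]
        raise ValidationError(f"relative humidity outside [0, 100]% at records {bad.tolist()}")
    vpd = saturation_vapor_pressure(t) * (1.0 - rh / 100.0)
    return vpd if vpd.ndim else float(vpd)


def atmospheric_pressure(elevation_m: float) -> float:
    """Barometric pressure (kPa) at a given elevation, standard-atmosphere form."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def psychrometric_constant(elevation_m: float) -> float:
    """Psychrometric constant gamma in kPa per deg C from site elevation."""
    return 0.665e-3 * atmospheric_pressure(elevation_m)


def wind_speed_at_2m(u_z, measurement_height_m: float):
    """Normalise wind speed measured at height z to the standard 2 m height."""
    if abs(measurement_height_m - 2.0) < 1e-9:
        return np.asarray(u_z, dtype=float)
    return np.asarray(u_z, dtype=float) * 4.87 / math.log(67.8 * measurement_height_m - 5.42)


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))  # sunset hour angle, clamped at polar limits
    return (
        24.0 * 60.0 / math.pi * SOLAR_CONSTANT * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )


def penman_monteith_daily(t_mean_c, rn, g, u2, es, ea, gamma):
    """Daily reference evapotranspiration (mm day-1), FAO-56 Penman-Monteith.

    ET0 = [0.408 D (Rn - G) + g 900/(T+273) u2 (es - ea)] / [D + g (1 + 0.34 u2)]

    with D the vapour-pressure-curve slope at the mean temperature, Rn and G in
    MJ m-2 day-1, u2 the 2-m wind in m s-1 and vapour pressures in kPa.
    Clipped at zero (condensation-dominated days report 0).
    """
    delta = slope_vapor_pressure_curve(t_mean_c)
    num = 0.408 * delta * (rn - g) + gamma * 900.0 / (np.asarray(t_mean_c) + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return float(np.maximum(num / den, 0.0))


def net_radiation_daily(
    rs_mj: float, t_max_c: float, t_min_c: float, ea: float, site: SiteMetadata, doy: int
) -> float:
    """Daily net radiation (MJ m-2 day-1) from measured shortwave radiation.

    Net shortwave uses the grass albedo 0.23; net longwave follows the FAO-56
    daily form with the relative shortwave ratio Rs/Rso capped at 1.
    """
    ra = extraterrestrial_radiation(site.latitude_deg, doy)
    rso = (0.75 + 2e-5 * site.elevation_m) * ra
    rns = (1.0 - ALBEDO) * rs_mj
    rel = min(rs_mj / rso, 1.0) if rso > 0 else 1.0
    rnl = (
        STEFAN_BOLTZMANN
        * (((t_max_c + 273.16) ** 4 + (t_min_c + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


# ---------------------------------------------------------------------------
# Daily aggregation
# ---------------------------------------------------------------------------


def _require_columns(day: pd.DataFrame, columns, day_label) -> None:
    missing = [c for c in columns if c not in day.columns or day[c].dropna().empty]
    if missing:
        raise ValidationError(f"day {day_label}: missing required weather variable(s) {missing}")


def compute_et0_daily(day: pd.DataFrame, site: SiteMetadata) -> float:
    """Daily FAO-56 Penman-Monteith ET0 (mm) from one calendar day of records.

    ``day`` holds sub-daily records with a DatetimeIndex and columns
    ``temp_c``, ``rh_pct``, ``solar_wm2``, ``wind_ms``.  Sub-daily inputs are
    aggregated to daily means/extremes/sums before the single daily
    evaluation: actual vapour pressure is the mean of the per-record
    es(T)*RH/100, daily es is the mean of es(Tmax) and es(Tmin), and measured
    shortwave radiation is integrated over the day.
    """
    if not isinstance(day.index, pd.DatetimeIndex):
        raise ValidationError("day slice must be indexed by timestamp")
    day_label = day.index[0].date() if len(day) else "<empty>"
    _require_columns(day, ("temp_c", "rh_pct", "solar_wm2", "wind_ms"), day_label)
    if (day["solar_wm2"].dropna() < 0).any():
        raise ValidationError(f"day {day_label}: negative solar radiation")

    t = day["temp_c"].dropna()
    t_max, t_min, t_mean = float(t.max()), float(t.min()), float(t.mean())
    es = float((saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min)) / 2.0)
    ea_series = saturation_vapor_pressure(day["temp_c"]) * day["rh_pct"] / 100.0
    ea = float(ea_series.dropna().mean())

    # integrate W m-2 over the record spacing -> MJ m-2 day-1
    dt_s = np.median(np.diff(day.index.view("int64"))) / 1e9 if len(day) > 1 else 600.0
    rs_mj = float(day["solar_wm2"].fillna(0.0).sum() * dt_s / 1e6)

    u2 = float(np.nanmean(wind_speed_at_2m(day["wind_ms"].to_numpy(), site.anemometer_height_m)))
    doy = int(day.index[0].dayofyear)
    rn = net_radiation_daily(rs_mj, t_max, t_min, ea, site, doy)
    gamma = psychrometric_constant(site.elevation_m)
    return penman_monteith_daily(t_mean, rn, 0.0, u2, es, min(ea, es), gamma)


def compute_etc(et0, coeffs: CropCoefficients):
    """Crop evapotranspiration ETc = Kcb*ET0 + Ke*ET0 = (Kcb + Ke)*ET0, in mm."""
    et0_arr = np.asarray(et0, dtype=float)
    if np.any(et0_arr < 0):
        raise ValidationError("ET0 must be >= 0")
    etc = (coeffs.kcb + coeffs.ke) * et0_arr
    return etc if etc.ndim else float(etc)


def daily_weather_summary(
    weather: pd.DataFrame, site: SiteMetadata, min_day_coverage: float = 0.8
) -> pd.DataFrame:
    """Collapse a sub-daily weather record to one row per calendar day.

    Returns a frame indexed by date with daily mean VPD (mean of per-record
    VPD, preserving diel asymmetry), daily ET0, rainfall total, record counts
    and a completeness flag: days with fewer than ``min_day_coverage`` of the
    expected records are flagged and excluded from stage aggregation.
    """
    if weather.empty:
        raise ValidationError("empty weather record")
    if not weather.index.is_monotonic_increasing or weather.index.has_duplicates:
        raise ValidationError("weather timestamps must be strictly increasing")
    step = pd.Timedelta(np.median(np.diff(weather.index.view("int64"))), unit="ns")
    expected = int(pd.Timedelta("1D") / step)
    vpd = compute_vpd(weather["temp_c"].to_numpy(), weather["rh_pct"].to_numpy())
    frame = weather.assign(vpd=vpd)
    rows = []
    for date, day in frame.groupby(frame.index.normalize()):
        coverage = len(day.dropna(subset=["temp_c", "rh_pct"])) / expected
        complete = coverage >= min_day_coverage
        rows.append(
            {
                "date": date,
                "n_records": len(day),
                "coverage": coverage,
                "complete": complete,
                "vpd_mean": float(day["vpd"].mean()) if complete else np.nan,
                "et0": compute_et0_daily(day, site) if complete else np.nan,
                "rain_mm": float(day.get("rain_mm", pd.Series(dtype=float)).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("date")


def aggregate_stage(
    weather: pd.DataFrame,
    stages: list[StageDefinition],
    bloom_date,
    site: SiteMetadata,
    coeffs: CropCoefficients | None = None,
    irrigation: dict[str, dict[str, float]] | None = None,
    min_day_coverage: float = 0.8,
) -> list[StageSummary]:
    """Aggregate a sub-daily weather record into per-stage summaries.

    Per stage: sigma_VPD = sum of daily mean VPD, sigma_ET0 = sum of daily ET0,
    and the mu values divide each by the stage duration in days; rainfall is
    summed.  Days failing the completeness threshold are excluded and counted
    (``days_with_data``).  ``irrigation`` optionally supplies per-treatment
    volumes keyed by stage_id; they are reported verbatim, not reconciled.
    """
    _check_stages(stages)
    bloom = pd.Timestamp(bloom_date).normalize()
    daily = daily_weather_summary(weather, site, min_day_coverage)
    summaries = []
    for stage in stages:
        start = bloom + pd.Timedelta(days=stage.start_dafb)
        end = bloom + pd.Timedelta(days=stage.end_dafb)
        window = daily.loc[(daily.index >= start) & (daily.index <= end)]
        if window.empty:
            raise ValidationError(f"stage {stage.stage_id} entirely outside the weather record")
        good = window[window["complete"]]
        vpd_sum = float(good["vpd_mean"].sum())
        et0_sum = float(good["et0"].sum())
        summaries.append(
            StageSummary(
                stage_id=stage.stage_id,
                duration_days=stage.duration_days,
                days_with_data=int(len(good)),
                rainfall_total=float(window["rain_mm"].sum()),
                vpd_mean_daily=vpd_sum / stage.duration_days,
                vpd_cumulative=vpd_sum,
                et0_mean_daily=et0_sum / stage.duration_days,
                et0_cumulative=et0_sum,
                etc_cumulative=float(compute_etc(et0_sum, coeffs)) if coeffs else None,
                irrigation_by_treatment=dict((irrigation or {}).get(stage.stage_id, {})),
            )
        )
    return summaries


def _check_stages(stages: list[StageDefinition]) -> None:
    for a, b in zip(stages, stages[1:]):
        if b.start_dafb <= a.end_dafb:
            raise ValidationError(f"stages {a.stage_id} and {b.stage_id} overlap or are unordered")


def stage_summaries_to_frame(summaries: list[StageSummary]) -> pd.DataFrame:
    """Tabulate stage summaries in seasonal-summary column order."""
    rows = []
    for s in summaries:
        row = {
            "stage": s.stage_id,
            "duration_days": s.duration_days,
            "days_with_data": s.days_with_data,
            "rainfall_mm": s.rainfall_total,
            "vpd_mean_kpa": s.vpd_mean_daily,
            "vpd_cum_kpa": s.vpd_cumulative,
            "et0_mean_mm": s.et0_mean_daily,
            "et0_cum_mm": s.et0_cumulative,
            "etc_cum_mm": s.etc_cumulative,
        }
        for treatment, volume in s.irrigation_by_treatment.items():
            row[f"irrigation_{treatment}_mm"] = volume
        rows.append(row)
    return pd.DataFrame(rows)


def load_weather_csv(path) -> pd.DataFrame:
    """Read a weather CSV (timestamp, temp_c, rh_pct, solar_wm2, wind_ms, rain_mm)."""
    frame = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"weather CSV missing columns {missing}")
    return frame
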