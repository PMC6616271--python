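"""Synthetic deficit-irrigation experiment generator.

Emulates the structure of a season-long stone-fruit deficit-irrigation trial:
four irrigation treatments (control, DI-40, DI-20, DI-0, i.e. 100/40/20/0 % of
crop evapotranspiration), four double-sigmoid fruit-growth stages (I, II,
IIIa, IIIb, default durations 36/50/29/31 days), a one-week 15-min sensor
deployment per stage (fruit dendrometer + leaf patch pressure probe, two
sensors per organ per tree, East/West tree orientations), spot physiology
curves at 3-h intervals, and a 10-min weather record.

Mechanisms emulated (and their limits):

* fruit diameter = double-sigmoid seasonal trend (sum of two logistic terms
  with a stage-II plateau) scaled by a treatment growth factor, minus a
  diurnal shrinkage bell whose amplitude grows linearly with midday stem
  water potential below a configurable onset, plus AR(1) noise;
* attenuated leaf patch pressure = baseline plus a diel bell peaking near
  solar noon (turgor loss), led (not lagged) relative to the fruit signal by
  ``fruit_leaf_lag_minutes`` — the phase relation that produces anticlockwise
  RPCR-vs-RGR loops;
* spot measurements satisfy the multilinear stem-water-potential relation by
  construction (stomatal conductance is solved from it), with independent
  leaf-to-leaf scatter and a configurable Gaussian residual on observed
  psi_stem;
* a feature-to-psi_stem calibration table is drawn from a configured "true"
  expo-linear form plus noise, giving the pipeline a known target for
  end-to-end parameter and threshold recovery.

Everything is driven by one integer seed through ``numpy.random.SeedSequence``
children in a fixed order, so identical configurations are byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ValidationError
from .models import REFERENCE_EXPOLINEAR_PARAMS, REFERENCE_STEM_WP_COEFS, detect_threshold, expolinear_curve
from .signals import SensorMeta, SensorSeries
from .weather import SiteMetadata, StageDefinition, compute_vpd


@dataclass(frozen=True)
class StageSpec:
    """One growth stage: DAFB interval plus its sensor-week and spot-curve days."""

    stage_id: str
    start_dafb: int
    end_dafb: int
    sensing_start_dafb: int
    spot_day_dafb: int

    def to_definition(self) -> StageDefinition:
        return StageDefinition(self.stage_id, self.start_dafb, self.end_dafb)


@dataclass(frozen=True)
class TreatmentSpec:
    """One irrigation treatment: target midday psi_stem per stage (MPa) and the
    relative final-fruit-size factor under that deficit."""

    name: str
    psi_midday: dict[str, float]
    growth_factor: float = 1.0


DEFAULT_STAGES = (
    StageSpec("I", 27, 62, 48, 50),
    StageSpec("II", 63, 112, 86, 92),
    StageSpec("IIIa", 113, 141, 127, 132),
    StageSpec("IIIb", 142, 172, 155, 155),
)

DEFAULT_TREATMENTS = (
    TreatmentSpec("control", {"I": -0.8, "II": -1.0, "IIIa": -1.2, "IIIb": -1.5}, 1.00),
    TreatmentSpec("DI-40", {"I": -1.0, "II": -1.1, "IIIa": -1.8, "IIIb": -2.3}, 0.96),
    # the two most severe treatments converge late in the season, when the
    # unwatered trees can no longer fall much further
    TreatmentSpec("DI-20", {"I": -1.1, "II": -1.2, "IIIa": -2.3, "IIIb": -3.2}, 0.93),
    TreatmentSpec("DI-0", {"I": -1.2, "II": -1.3, "IIIa": -2.9, "IIIb": -3.5}, 0.90),
)

SPOT_HOURS = (5.0, 7.0, 10.0, 13.0, 16.0, 19.0)  # pre-dawn then 3-h intervals


@dataclass
class ScenarioConfig:
    """Full parameterisation of a synthetic experiment."""

    seed: int = 0
    bloom_date: str = "2017-10-15"
    stages: tuple[StageSpec, ...] = DEFAULT_STAGES
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS
    n_trees_per_treatment: int = 2
    sensors_per_organ: int = 2
    week_days: int = 7
    site: SiteMetadata = field(default_factory=lambda: SiteMetadata(latitude_deg=-36.4, elevation_m=113.0))

    # double-sigmoid fruit growth (mm; DAFB time axis)
    fd_base_mm: float = 8.0
    sigmoid1: tuple[float, float, float] = (30.0, 45.0, 9.0)  # amplitude, midpoint, scale
    sigmoid2: tuple[float, float, float] = (21.0, 135.0, 8.0)

    # deficit response of within-stage growth: the growth accrued during a
    # sensing week is scaled by max(0, 1 - slope * deficit below onset)
    deficit_growth_slope: float = 0.4

    # diel components
    fruit_diel_amp_mm: float = 0.15
    leaf_pp_baseline_kpa: float = 120.0
    leaf_diel_amp_kpa: float = 25.0
    amp_deficit_onset_mpa: float = -1.0
    amp_deficit_slope: float = 0.6  # relative amplitude gain per MPa below onset
    fruit_leaf_lag_minutes: float = 90.0  # leaf signal leads fruit by this much

    # noise
    ar1: float = 0.8
    fruit_noise_sd_mm: float = 0.01
    leaf_noise_sd_kpa: float = 0.4
    sensor_offset_sd_mm: float = 1.5
    psi_noise_sd: float = 0.24  # residual of observed psi_stem around the multilinear relation
    leaf_scatter_sd: float = 0.08  # leaf-to-leaf psi_leaf variability (MPa)
    tree_psi_sd: float = 0.25  # tree-week midday psi_stem spread around the treatment target (MPa)
    ratio_noise_sd: float = 0.03  # day-to-day scatter of the nocturnal RSD ratio

    # calibration truth for the feature-to-psi_stem link
    expolinear_truth: dict = field(default_factory=lambda: dict(REFERENCE_EXPOLINEAR_PARAMS))

    weather_gap_dafb: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if abs(self.fruit_leaf_lag_minutes) > 360:
            raise ValidationError("fruit-leaf lag must be within +-6 h")
        if self.fruit_diel_amp_mm < 0 or self.leaf_diel_amp_kpa < 0:
            raise ValidationError("diel amplitudes must be >= 0")

    @property
    def bloom(self) -> pd.Timestamp:
        return pd.Timestamp(self.bloom_date)

    def stage(self, stage_id: str) -> StageSpec:
        for s in self.stages:
            if s.stage_id == stage_id:
                return s
        raise ValidationError(f"unknown stage {stage_id!r}")

    def treatment(self, name: str) -> TreatmentSpec:
        for t in self.treatments:
            if t.name == name:
                return t
        raise ValidationError(f"unknown treatment {name!r}")


# ---------------------------------------------------------------------------
# Deterministic sub-seeding
# ---------------------------------------------------------------------------


def _rng(config: ScenarioConfig, *key) -> np.random.Generator:
    """A generator keyed by (seed, component key) — order-independent determinism.

    The component key is reduced with CRC-32 (stable across processes, unlike
    the builtin hash) so each generated object has its own reproducible stream.
    """
    digest = zlib.crc32("/".join(map(str, key)).encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, digest]))


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 autocorrelation rho and marginal sd."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    out = lfilter([1.0], [1.0, -rho], eps)
    return np.asarray(out)


def _solar_bell(hours: np.ndarray, rise: float = 6.0, span: float = 14.0) -> np.ndarray:
    """Half-sine daytime bell: 0 at night, 1 near solar noon."""
    phase = (hours - rise) / span
    return np.where((phase > 0) & (phase < 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------


def gen_weather(config: ScenarioConfig) -> pd.DataFrame:
    """10-min weather series over the whole season (first to last stage DAFB).

    Sinusoidal seasonal and diel temperature with AR(1) noise, humidity
    inversely tracking temperature, clear-sky solar radiation modulated by
    per-day cloudiness, light wind, and sporadic rain.  An optional DAFB gap
    mimics a logger outage.
    """
    rng = _rng(config, "weather")
    start = config.bloom + pd.Timedelta(days=config.stages[0].start_dafb)
    end = config.bloom + pd.Timedelta(days=config.stages[-1].end_dafb + 1)
    index = pd.date_range(start, end, freq="10min", inclusive="left")
    dafb = (index - config.bloom) / pd.Timedelta(days=1)
    hours = index.hour + index.minute / 60.0
    season = np.sin(np.pi * (dafb - config.stages[0].start_dafb) / (config.stages[-1].end_dafb - config.stages[0].start_dafb))
    t_daily_mean = 17.0 + 8.0 * season
    temp = (
        t_daily_mean
        + 7.0 * np.cos(2.0 * np.pi * (hours - 14.0) / 24.0)
        + _ar1(rng, len(index), config.ar1, 0.8)
    )
    rh = np.clip(88.0 - 2.2 * (temp - t_daily_mean) - 14.0 * season + _ar1(rng, len(index), config.ar1, 3.0), 20.0, 100.0)

    day_key = index.normalize()
    n_days = day_key.nunique()
    cloud_draw = rng.uniform(size=n_days)
    cloud_factor = np.where(cloud_draw < 0.25, rng.uniform(0.25, 0.7, n_days), 1.0 - 0.08 * rng.uniform(size=n_days))
    cloud_by_day = pd.Series(cloud_factor, index=day_key.unique())
    solar = cloud_by_day.loc[day_key].to_numpy() * (650.0 + 300.0 * season) * _solar_bell(np.asarray(hours))

    wind = np.clip(1.6 + _ar1(rng, len(index), config.ar1, 0.5), 0.1, None)

    rain = np.zeros(len(index))
    rain_days = rng.uniform(size=n_days) < 0.18
    amounts = rng.exponential(6.0, n_days) * rain_days
    for day, amount in zip(cloud_by_day.index[amounts > 0], amounts[amounts > 0]):
        sel = np.flatnonzero((day_key == day) & (hours >= 16) & (hours < 20))
        if sel.size:
            rain[sel] = amount / sel.size

    frame = pd.DataFrame(
        {"temp_c": temp, "rh_pct": rh, "solar_wm2": solar, "wind_ms": wind, "rain_mm": rain},
        index=index,
    )
    frame.index.name = "timestamp"
    if config.weather_gap_dafb is not None:
        lo, hi = config.weather_gap_dafb
        frame = frame[(dafb < lo) | (dafb > hi + 1)]
    return frame


# ---------------------------------------------------------------------------
# Sensor signals
# ---------------------------------------------------------------------------


def double_sigmoid(dafb, base: float, sig1, sig2) -> np.ndarray:
    """Seasonal fruit diameter: base + two logistic waves with a stage-II plateau."""
    d = np.asarray(dafb, dtype=float)
    a1, m1, s1 = sig1
    a2, m2, s2 = sig2
    return base + a1 / (1.0 + np.exp(-(d - m1) / s1)) + a2 / (1.0 + np.exp(-(d - m2) / s2))


def _deficit_gain(psi_midday: float, config: ScenarioConfig) -> float:
    return 1.0 + config.amp_deficit_slope * max(0.0, config.amp_deficit_onset_mpa - psi_midday)


def _week_index(config: ScenarioConfig, stage: StageSpec) -> pd.DatetimeIndex:
    start = config.bloom + pd.Timedelta(days=stage.sensing_start_dafb)
    return pd.date_range(start, periods=config.week_days * 96, freq="15min")


def gen_fruit_series(
    config: ScenarioConfig, treatment: str, tree_id: str, stage_id: str, sensor: int = 0
) -> SensorSeries:
    """One fruit-gauge week: seasonal growth minus diurnal shrinkage plus noise.

    The diurnal shrinkage amplitude grows with water deficit; the treatment
    growth factor shrinks the seasonal gain so deficit fruit end smaller.
    """
    stage = config.stage(stage_id)
    spec = config.treatment(treatment)
    index = _week_index(config, stage)
    rng = _rng(config, "fruit", treatment, tree_id, stage_id, sensor)
    dafb = (index - config.bloom) / pd.Timedelta(days=1)
    hours = np.asarray(index.hour + index.minute / 60.0)

    psi = spec.psi_midday[stage_id]
    season = config.fd_base_mm + spec.growth_factor * (
        double_sigmoid(dafb, 0.0, config.sigmoid1, config.sigmoid2)
    )
    # deficit stalls expansion within the sensing week (severe deficit -> flat)
    week_gain = max(0.0, 1.0 - config.deficit_growth_slope * max(0.0, config.amp_deficit_onset_mpa - psi))
    trend = season[0] + week_gain * (season - season[0])
    amp = config.fruit_diel_amp_mm * _deficit_gain(psi, config)
    diel = -amp * _solar_bell(hours)
    offset = rng.normal(0.0, config.sensor_offset_sd_mm)
    noise = _ar1(rng, len(index), config.ar1, config.fruit_noise_sd_mm)
    values = pd.Series(trend + diel + offset + noise, index=index)
    if (values <= 0).any():
        raise ValidationError("generated fruit diameters must stay positive; adjust config")
    meta = SensorMeta(
        organ="fruit", tree_id=tree_id, treatment=treatment, stage_id=stage_id,
        orientation="East" if int(tree_id[-1]) % 2 == 0 else "West", sensor_id=f"FG{sensor}",
    )
    return SensorSeries(values=values, meta=meta, history=["synthetic"])


def gen_leaf_pp_series(
    config: ScenarioConfig, treatment: str, tree_id: str, stage_id: str, sensor: int = 0
) -> SensorSeries:
    """One leaf-probe week: baseline plus a noon turgor-loss bell plus noise.

    The bell is shifted *earlier* by the configured fruit-leaf lag (the leaf
    signal leads the fruit signal), which makes the diel RPCR-vs-RGR
    trajectory anticlockwise; its amplitude grows with deficit and the
    attenuated pressure therefore swings more in stressed trees.
    """
    stage = config.stage(stage_id)
    spec = config.treatment(treatment)
    index = _week_index(config, stage)
    rng = _rng(config, "leaf", treatment, tree_id, stage_id, sensor)
    hours = np.asarray(index.hour + index.minute / 60.0)

    psi = spec.psi_midday[stage_id]
    amp = config.leaf_diel_amp_kpa * _deficit_gain(psi, config)
    bell = _solar_bell(hours + config.fruit_leaf_lag_minutes / 60.0)
    baseline = config.leaf_pp_baseline_kpa * (1.0 + rng.normal(0.0, 0.05))
    noise = _ar1(rng, len(index), config.ar1, config.leaf_noise_sd_kpa)
    values = pd.Series(baseline + amp * bell + noise, index=index)
    if (values <= 0).any():
        raise ValidationError("generated patch pressures must stay positive; adjust config")
    meta = SensorMeta(
        organ="leaf", tree_id=tree_id, treatment=treatment, stage_id=stage_id,
        orientation="East" if int(tree_id[-1]) % 2 == 0 else "West", sensor_id=f"LP{sensor}",
    )
    return SensorSeries(values=values, meta=meta, history=["synthetic"])


# ---------------------------------------------------------------------------
# Spot physiology
# ---------------------------------------------------------------------------


def _psi_stem_curve(psi_midday: float, hours: np.ndarray) -> np.ndarray:
    """Diel stem-water-potential curve: pre-dawn maximum, solar-noon minimum."""
    psi_predawn = -0.2 + 0.35 * psi_midday
    bell = _solar_bell(hours, rise=7.0, span=12.0)
    return psi_predawn + (psi_midday - psi_predawn) * bell


def gen_spot_measurements(config: ScenarioConfig, weather: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spot physiology table: per treatment, tree, stage and 3-h daytime slot.

    psi_leaf sits below psi_stem by a VPD-scaled offset (vanishing pre-dawn);
    stomatal conductance is solved from the multilinear stem-water-potential
    relation so the generated table satisfies it up to the configured
    Gaussian residual on observed psi_stem; leaf relative water content is a
    bounded linear map of psi_leaf.
    """
    if weather is None:
        weather = gen_weather(config)
    vpd = pd.Series(
        compute_vpd(weather["temp_c"].to_numpy(), weather["rh_pct"].to_numpy()), index=weather.index
    )
    b = REFERENCE_STEM_WP_COEFS
    rows = []
    for spec in config.treatments:
        for tree in range(config.n_trees_per_treatment):
            tree_id = f"{spec.name}-T{tree}"
            rng = _rng(config, "spots", spec.name, tree_id)
            for stage in config.stages:
                day = config.bloom + pd.Timedelta(days=stage.spot_day_dafb)
                hours = np.asarray(SPOT_HOURS)
                psi_true = _psi_stem_curve(spec.psi_midday[stage.stage_id], hours)
                for h, psi in zip(hours, psi_true):
                    ts = day + pd.Timedelta(hours=h)
                    pos = vpd.index.get_indexer([ts], method="nearest")[0]
                    v = float(vpd.iloc[pos]) if pos >= 0 else 0.5
                    psi_leaf = psi - (0.05 + 0.25 * v) + rng.normal(0.0, config.leaf_scatter_sd)
                    gs = (psi - b["intercept"] - b["psi_leaf"] * psi_leaf - b["vpd"] * v) / b["gs"]
                    gs = max(gs, 0.0)
                    rows.append(
                        {
                            "timestamp": ts,
                            "tree_id": tree_id,
                            "treatment": spec.name,
                            "stage_id": stage.stage_id,
                            "psi_stem": psi + rng.normal(0.0, config.psi_noise_sd),
                            "psi_stem_true": psi,
                            "psi_leaf": psi_leaf,
                            "gs": gs,
                            "rwc": float(np.clip(98.0 + 5.5 * psi_leaf + rng.normal(0.0, 1.0), 55.0, 100.0)),
                            "vpd": v,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature calibration pairs and the experiment bundle
# ---------------------------------------------------------------------------


def gen_feature_pairs(config: ScenarioConfig) -> pd.DataFrame:
    """Per-day nocturnal RSD-ratio vs midday psi_stem calibration table.

    One row per treatment x stage x tree x sensing day.  The tree-week midday
    psi_stem is the treatment's stage target plus tree-week variability
    (``tree_psi_sd``, matching typical between-tree spread); the daily ratio
    follows the configured true expo-linear form at that psi plus day-to-day
    Gaussian scatter (``ratio_noise_sd``).  Regressions use the tree-week
    means (``tree_week_means``), the unit the seasonal pooling works at.
    """
    rng = _rng(config, "feature_pairs")
    rows = []
    for spec in config.treatments:
        for stage in config.stages:
            for tree in range(config.n_trees_per_treatment):
                psi = spec.psi_midday[stage.stage_id] + rng.normal(0.0, config.tree_psi_sd)
                ratios = expolinear_curve(psi, **config.expolinear_truth) + rng.normal(
                    0.0, config.ratio_noise_sd, config.week_days
                )
                for day, ratio in enumerate(ratios):
                    rows.append(
                        {
                            "treatment": spec.name,
                            "stage_id": stage.stage_id,
                            "tree_id": f"{spec.name}-T{tree}",
                            "day": day,
                            "psi_stem_midday": psi,
                            "nocturnal_rsd_ratio": float(ratio),
                        }
                    )
    return pd.DataFrame(rows)


def tree_week_means(pairs: pd.DataFrame) -> pd.DataFrame:
    """Average per-day calibration rows to one row per tree-week."""
    return (
        pairs.groupby(["treatment", "stage_id", "tree_id"], as_index=False)[
            ["psi_stem_midday", "nocturnal_rsd_ratio"]
        ].mean()
    )


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produced, plus its ground truth."""

    config: ScenarioConfig
    weather: pd.DataFrame
    sensors: dict[tuple, SensorSeries]
    spots: pd.DataFrame
    feature_pairs: pd.DataFrame
    ground_truth: dict

    def write(self, outdir) -> Path:
        """Write the bundle as the CSV dialects the ingestion functions read."""
        out = Path(outdir)
        (out / "sensors").mkdir(parents=True, exist_ok=True)
        self.weather.reset_index().to_csv(out / "weather.csv", index=False)
        self.spots.to_csv(out / "spots.csv", index=False)
        self.feature_pairs.to_csv(out / "feature_pairs.csv", index=False)
        for (treatment, tree_id, stage_id, organ, sensor), series in self.sensors.items():
            name = f"{treatment}_{tree_id}_{stage_id}_{organ}{sensor}.csv"
            series.values.rename("value").rename_axis("timestamp").reset_index().to_csv(
                out / "sensors" / name, index=False
            )
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2, default=float))
        return out


def gen_experiment(config: ScenarioConfig | None = None) -> ExperimentBundle:
    """Generate the full dataset bundle for one scenario.

    Returns weather, all sensor weeks (treatment x stage x tree x organ x
    sensor), the spot table, the feature calibration pairs and the ground
    truth needed by recovery tests.
    """
    config = config or ScenarioConfig()
    weather = gen_weather(config)
    sensors: dict[tuple, SensorSeries] = {}
    for spec in config.treatments:
        for tree in range(config.n_trees_per_treatment):
            tree_id = f"{spec.name}-T{tree}"
            for stage in config.stages:
                for sensor in range(config.sensors_per_organ):
                    sensors[(spec.name, tree_id, stage.stage_id, "fruit", sensor)] = gen_fruit_series(
                        config, spec.name, tree_id, stage.stage_id, sensor
                    )
                    sensors[(spec.name, tree_id, stage.stage_id, "leaf", sensor)] = gen_leaf_pp_series(
                        config, spec.name, tree_id, stage.stage_id, sensor
                    )
    spots = gen_spot_measurements(config, weather)
    pairs = gen_feature_pairs(config)
    truth_threshold = detect_threshold(config.expolinear_truth).psi_threshold
    ground_truth = {
        "psi_midday": {t.name: dict(t.psi_midday) for t in config.treatments},
        "expolinear": dict(config.expolinear_truth),
        "psi_threshold": truth_threshold,
        "stem_wp_coefs": dict(REFERENCE_STEM_WP_COEFS),
        "fruit_leaf_lag_minutes": config.fruit_leaf_lag_minutes,
        "seed": config.seed,
    }
    return ExperimentBundle(config, weather, sensors, spots, pairs, ground_truth)
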