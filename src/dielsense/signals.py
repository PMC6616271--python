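"""Continuous sensor signals: ingestion, QC, smoothing, z-scores and rate transforms.

The two organ signals are the fruit diameter FD (mm, from an LVDT fruit gauge)
and the attenuated leaf-patch pressure p_p (kPa, from a leaf patch clamp
pressure probe; inversely related to leaf cell turgor).  Both live on a 15-min
grid.  The pipeline is: load -> QC filter -> smooth (15-point degree-3
least-squares polynomial convolution, i.e. Savitzky-Golay) -> either z-score
standardisation (for cross-sensor comparison of FD / p_p themselves) or the
log-difference rate transforms

    RGR_k  = ln FD(t_{k+1}) - ln FD(t_k)        (per 15-min interval)
    RPCR_k = ln p_p(t_{k+1}) - ln p_p(t_k)

which are scale-free and therefore not standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import QCError, ValidationError

GRID = pd.Timedelta("15min")

#: qc flag codes
QC_OK = 0
QC_NONPOSITIVE = 1
QC_SPIKE = 2
QC_DISPLACED = 3
QC_UNSMOOTHED = 4

ORGAN_SIGNALS = {"fruit": "fruit_diameter", "leaf": "patch_pressure"}


@dataclass(frozen=True)
class SensorMeta:
    """Provenance of one sensor deployment."""

    organ: str
    tree_id: str = ""
    treatment: str = ""
    stage_id: str = ""
    orientation: str = ""
    sensor_id: str = ""

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_SIGNALS:
            raise ValidationError(f"organ must be one of {sorted(ORGAN_SIGNALS)}, got {self.organ!r}")

    @property
    def signal_kind(self) -> str:
        return ORGAN_SIGNALS[self.organ]


@dataclass
class SensorSeries:
    """One organ's 15-min signal with per-point QC flags.

    ``values`` is a pandas Series on a regular 15-min DatetimeIndex with NaN
    for explicit gaps; ``qc_flags`` is an integer Series on the same index.
    """

    values: pd.Series
    meta: SensorMeta
    is_smoothed: bool = False
    qc_flags: pd.Series | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex) or not idx.is_monotonic_increasing:
            raise ValidationError("sensor series needs an increasing DatetimeIndex")
        if len(idx) > 1:
            deltas = np.diff(idx.view("int64"))
            if not np.all(deltas == GRID.value):
                raise ValidationError("sensor series must be on a regular 15-min grid")
        if self.qc_flags is None:
            self.qc_flags = pd.Series(QC_OK, index=idx, dtype=int)

    @property
    def valid_mask(self) -> pd.Series:
        return self.values.notna() & self.qc_flags.isin([QC_OK, QC_UNSMOOTHED])

    @property
    def valid_values(self) -> pd.Series:
        return self.values[self.valid_mask]

    @property
    def excluded_fraction(self) -> float:
        flagged = int(((self.qc_flags != QC_OK) & (self.qc_flags != QC_UNSMOOTHED)).sum())
        return flagged / len(self.values) if len(self.values) else 0.0


@dataclass
class StandardizedSeries:
    """z-scored signal: z = (x - mean) / sd over a declared window (sample sd)."""

    z: pd.Series
    meta: SensorMeta
    window: tuple[pd.Timestamp, pd.Timestamp]
    mean: float
    sd: float


@dataclass
class RateSeries:
    """Log-difference rate series (RGR for fruit, RPCR for leaf), per 15-min interval.

    Values are indexed by the *end* timestamp of each interval, so the series
    has one fewer point than its source.
    """

    values: pd.Series
    rate_kind: str
    meta: SensorMeta
    per: str = "interval"


def _snap_to_grid(ts: pd.Series, tolerance: pd.Timedelta) -> pd.Series:
    floor = ts.dt.floor("15min")
    ceil = ts.dt.ceil("15min")
    to_floor = ts - floor
    to_ceil = ceil - ts
    snapped = floor.where(to_floor <= to_ceil, ceil)
    off = abs(ts - snapped) > tolerance
    return snapped.where(~off, pd.NaT)


def load_sensor_csv(path, meta: SensorMeta, value_column: str = "value") -> SensorSeries:
    """Load a sensor CSV (timestamp, value[, sensor_id]) onto the 15-min grid.

    Off-grid timestamps are snapped when within +-90 s of a grid point and
    rejected otherwise; duplicates after snapping are an error; non-positive
    values are flagged (the log transform needs positive signals) and gaps
    become explicit NaNs on the full grid from first to last record.
    """
    raw = pd.read_csv(path)
    if "timestamp" not in raw.columns or value_column not in raw.columns:
        raise ValidationError(f"{path}: needs 'timestamp' and {value_column!r} columns")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"], format="mixed")
    snapped = _snap_to_grid(raw["timestamp"], pd.Timedelta(seconds=90))
    keep = snapped.notna()
    frame = pd.DataFrame({"timestamp": snapped[keep], "value": raw.loc[keep, value_column]})
    if frame["timestamp"].duplicated().any():
        dups = frame.loc[frame["timestamp"].duplicated(), "timestamp"].head(3).tolist()
        raise ValidationError(f"{path}: duplicate timestamps after grid snapping, e.g. {dups}")
    frame = frame.set_index("timestamp").sort_index()
    grid = pd.date_range(frame.index.min(), frame.index.max(), freq="15min")
    values = frame["value"].reindex(grid).astype(float)
    flags = pd.Series(QC_OK, index=grid, dtype=int)
    nonpos = values.notna() & (values <= 0)
    flags[nonpos] = QC_NONPOSITIVE
    values[nonpos] = np.nan
    return SensorSeries(values=values, meta=meta, qc_flags=flags, history=[f"loaded {path}"])


def qc_filter(
    series: SensorSeries,
    max_excluded_fraction: float = 0.05,
    spike_factor: float = 10.0,
) -> SensorSeries:
    """Flag spikes and displacement steps; reject series losing too many points.

    A point is a *spike* when both adjacent 15-min steps exceed
    ``spike_factor`` times the series' median absolute step and have opposite
    signs (the signal jumps and returns); a *displacement* is a single
    threshold-crossing step (a persistent offset, typically a wind-moved
    sensor) whose landing point is flagged.  If the overall excluded fraction
    reaches ``max_excluded_fraction`` the series is rejected with a QCError.
    """
    values = series.values.copy()
    flags = series.qc_flags.copy()
    v = values.to_numpy()
    steps = np.diff(v)
    finite = np.abs(steps[np.isfinite(steps)])
    if finite.size:
        scale = np.median(finite)
        threshold = spike_factor * max(scale, 1e-12)
        for i in range(1, len(v) - 1):
            d1, d2 = steps[i - 1], steps[i]
            if not (np.isfinite(d1) and np.isfinite(d2)):
                continue
            if abs(d1) > threshold and abs(d2) > threshold and np.sign(d1) != np.sign(d2):
                flags.iloc[i] = QC_SPIKE
            elif abs(d1) > threshold and flags.iloc[i] == QC_OK:
                flags.iloc[i] = QC_DISPLACED
    bad = flags.isin([QC_SPIKE, QC_DISPLACED, QC_NONPOSITIVE])
    excluded = int(bad.sum()) / len(values) if len(values) else 0.0
    if excluded >= max_excluded_fraction:
        raise QCError(
            f"{series.meta.organ} sensor {series.meta.sensor_id or '?'}: "
            f"{excluded:.1%} of points flagged (>= {max_excluded_fraction:.0%} limit)"
        )
    values[bad] = np.nan
    return replace(
        series,
        values=values,
        qc_flags=flags,
        history=series.history + [f"qc_filter excluded {excluded:.4f}"],
    )


def _contiguous_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True runs in a boolean array."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    yield from zip(starts, stops)


def smooth_series(series: SensorSeries, window_points: int = 15, polyorder: int = 3) -> SensorSeries:
    """Smooth each contiguous valid segment with a centred least-squares
    polynomial convolution filter (Savitzky-Golay), window 15 points, degree 3.

    Edge points are handled by polynomial extrapolation of the terminal window
    fits, which preserves polynomials up to the filter degree exactly.
    Segments shorter than the window pass through unsmoothed with a warning
    flag.
    """
    values = series.values.copy()
    flags = series.qc_flags.copy()
    v = values.to_numpy(copy=True)
    mask = np.isfinite(v)
    for start, stop in _contiguous_runs(mask):
        if stop - start >= window_points:
            v[start:stop] = savgol_filter(v[start:stop], window_points, polyorder, mode="interp")
        else:
            sel = flags.iloc[start:stop] == QC_OK
            flags.iloc[start:stop] = np.where(sel, QC_UNSMOOTHED, flags.iloc[start:stop])
    values[:] = v
    return replace(
        series,
        values=values,
        is_smoothed=True,
        qc_flags=flags,
        history=series.history + [f"savgol window={window_points} degree={polyorder}"],
    )


def standardize(obj, window: tuple | None = None) -> StandardizedSeries:
    """z-score a sensor series over a time window: z = (x - mean) / sd.

    ``sd`` is the sample (n-1) standard deviation.  The window defaults to the
    full series span ("the specific time interval used for the calculation"
    being the whole deployment); pass ``(start, stop)`` timestamps to
    standardise per-day or per-stage.  Idempotent: standardising an already
    standardised series returns the same z-values.
    """
    if isinstance(obj, StandardizedSeries):
        values, meta = obj.z, obj.meta
    else:
        values, meta = obj.values, obj.meta
    if window is None:
        window = (values.index[0], values.index[-1])
    start, stop = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    in_window = values.loc[start:stop].dropna()
    if len(in_window) < 2:
        raise ValidationError(f"standardization window [{start}, {stop}] has < 2 valid points")
    mean = float(in_window.mean())
    sd = float(in_window.std(ddof=1))
    if sd == 0.0:
        raise ValidationError(f"flat series in standardization window [{start}, {stop}]")
    return StandardizedSeries(z=(values - mean) / sd, meta=meta, window=(start, stop), mean=mean, sd=sd)


def _log_difference(series: SensorSeries, per: str) -> pd.Series:
    v = series.values.copy()
    v[v <= 0] = np.nan  # log undefined; those intervals become gaps
    rate = np.log(v).diff().iloc[1:]
    if per == "hour":
        rate = rate * 4.0
    elif per != "interval":
        raise ValidationError("per must be 'interval' or 'hour'")
    return rate


def compute_rgr(series: SensorSeries, per: str = "interval") -> RateSeries:
    """Fruit relative growth rate: first log-difference of smoothed FD.

    RGR_k = [ln FD(t_{k+1}) - ln FD(t_k)] / (t_{k+1} - t_k), with the 15-min
    interval as the time unit (``per='hour'`` multiplies by 4).  Invariant
    under multiplicative rescaling of the diameter; equals the exponential
    growth rate exactly for FD(t) = A e^{rt}.
    """
    if series.meta.organ != "fruit":
        raise ValidationError("RGR is defined on the fruit-diameter signal")
    return RateSeries(values=_log_difference(series, per), rate_kind="RGR", meta=series.meta, per=per)


def compute_rpcr(series: SensorSeries, per: str = "interval") -> RateSeries:
    """Leaf relative pressure change rate: first log-difference of smoothed p_p.

    Positive RPCR means rising attenuated patch pressure, i.e. falling leaf
    turgor.
    """
    if series.meta.organ != "leaf":
        raise ValidationError("RPCR is defined on the leaf patch-pressure signal")
    return RateSeries(values=_log_difference(series, per), rate_kind="RPCR", meta=series.meta, per=per)


def average_standardized(series_list: list[StandardizedSeries]) -> pd.Series:
    """Average z-scores of several sensors of a tree at matching timestamps."""
    if not series_list:
        raise ValidationError("nothing to average")
    return pd.concat([s.z for s in series_list], axis=1).mean(axis=1)


def average_rates(rate_list: list[RateSeries]) -> RateSeries:
    """Average raw rates of several sensors of a tree at matching timestamps."""
    if not rate_list:
        raise ValidationError("nothing to average")
    kinds = {r.rate_kind for r in rate_list}
    if len(kinds) > 1:
        raise ValidationError(f"cannot mix rate kinds {sorted(kinds)}")
    merged = pd.concat([r.values for r in rate_list], axis=1).mean(axis=1)
    return RateSeries(values=merged, rate_kind=rate_list[0].rate_kind, meta=rate_list[0].meta, per=rate_list[0].per)
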