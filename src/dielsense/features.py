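"""Diel / diurnal / nocturnal windowing and per-window summary features.

Clock-time windows on the 15-min grid:

* diurnal:   07:00-19:45 (52 slots), anchored to its calendar date;
* nocturnal: 20:00-06:45 of the following morning (44 slots), anchored to the
  evening date;
* diel:      the union of a date's diurnal and nocturnal windows
  (07:00 -> 06:45 next day, 96 slots), so diurnal + nocturnal tile the diel
  window exactly.

Per window the features are the relative standard deviation
RSD = sd / |mean| (sample sd), maximum, minimum, sum and mean, reported only
when the window holds at least a configurable fraction of its expected slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DIURNAL_START = pd.Timedelta(hours=7)
DIURNAL_END = pd.Timedelta(hours=19, minutes=45)
NOCTURNAL_START = pd.Timedelta(hours=20)

WINDOW_KINDS = ("diel", "diurnal", "nocturnal")
EXPECTED_SLOTS = {"diel": 96, "diurnal": 52, "nocturnal": 44}


@dataclass(frozen=True)
class DielWindow:
    """One anchored window: kind plus the calendar date it starts on."""

    window_kind: str
    date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.window_kind not in WINDOW_KINDS:
            raise ValidationError(f"unknown window kind {self.window_kind!r}")

    @property
    def n_expected(self) -> int:
        return EXPECTED_SLOTS[self.window_kind]


@dataclass
class WindowFeatures:
    """Summary statistics of one series over one window."""

    window: DielWindow
    rsd: float
    vmax: float
    vmin: float
    vsum: float
    mean: float
    n_valid: int
    flags: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return "incomplete" not in self.flags


@dataclass
class FeatureRatio:
    """Fruit-to-leaf ratio of one named statistic over matching windows."""

    stat: str
    window: DielWindow
    value: float | None


def assign_windows(index: pd.DatetimeIndex) -> pd.DataFrame:
    """Assign every timestamp to exactly one diurnal or nocturnal window.

    Times in 07:00-19:45 are diurnal on their own date; all other times are
    nocturnal, anchored to the evening date (pre-dawn points belong to the
    previous evening's window).
    """
    tod = index - index.normalize()
    diurnal = (tod >= DIURNAL_START) & (tod <= DIURNAL_END)
    anchor = index.normalize().where(tod >= DIURNAL_START, index.normalize() - pd.Timedelta(days=1))
    return pd.DataFrame(
        {
            "window_kind": np.where(diurnal, "diurnal", "nocturnal"),
            "anchor_date": anchor,
        },
        index=index,
    )


def partition_windows(values: pd.Series) -> dict[DielWindow, pd.Series]:
    """Split a 15-min series into anchored diurnal and nocturnal segments."""
    assignment = assign_windows(values.index)
    segments: dict[DielWindow, pd.Series] = {}
    for (kind, date), group in assignment.groupby(["window_kind", "anchor_date"], sort=True):
        segments[DielWindow(str(kind), pd.Timestamp(date))] = values.loc[group.index]
    return segments


def window_stats(
    segment: pd.Series,
    window: DielWindow,
    completeness_min: float = 0.8,
    mean_eps: float = 1e-12,
) -> WindowFeatures:
    """Compute RSD, max, min, sum and mean of one window segment.

    Features are null (NaN) when fewer than ``completeness_min`` of the
    window's expected slots hold valid values; RSD alone is null-flagged when
    |mean| falls below ``mean_eps`` (division would be meaningless, not
    infinite).
    """
    valid = segment.dropna()
    n_valid = int(len(valid))
    flags: list[str] = []
    if n_valid / window.n_expected < completeness_min:
        return WindowFeatures(window, np.nan, np.nan, np.nan, np.nan, np.nan, n_valid, ("incomplete",))
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1)) if n_valid > 1 else 0.0
    if abs(mean) < mean_eps:
        rsd = np.nan
        flags.append("zero_mean")
    else:
        rsd = sd / abs(mean)
    return WindowFeatures(
        window=window,
        rsd=rsd,
        vmax=float(valid.max()),
        vmin=float(valid.min()),
        vsum=float(valid.sum()),
        mean=mean,
        n_valid=n_valid,
        flags=tuple(flags),
    )


def compute_window_features(
    values: pd.Series,
    completeness_min: float = 0.8,
    kinds: tuple[str, ...] = WINDOW_KINDS,
) -> pd.DataFrame:
    """Per-day window features of a series, one row per (date, window kind).

    The diel row of a date aggregates that date's diurnal and nocturnal
    segments (07:00 through 06:45 the next morning).
    """
    segments = partition_windows(values)
    by_date: dict[pd.Timestamp, dict[str, pd.Series]] = {}
    for window, segment in segments.items():
        by_date.setdefault(window.date, {})[window.window_kind] = segment
    rows = []
    for date in sorted(by_date):
        parts = by_date[date]
        candidates = dict(parts)
        if "diel" in kinds:
            pieces = [parts[k] for k in ("diurnal", "nocturnal") if k in parts and not parts[k].empty]
            if pieces:
                candidates["diel"] = pd.concat(pieces).sort_index()
        for kind in kinds:
            if kind not in candidates:
                continue
            wf = window_stats(candidates[kind], DielWindow(kind, date), completeness_min)
            rows.append(
                {
                    "date": date,
                    "window_kind": kind,
                    "rsd": wf.rsd,
                    "max": wf.vmax,
                    "min": wf.vmin,
                    "sum": wf.vsum,
                    "mean": wf.mean,
                    "n_valid": wf.n_valid,
                    "flags": ";".join(wf.flags),
                }
            )
    return pd.DataFrame(rows)


def feature_ratio(fruit: WindowFeatures, leaf: WindowFeatures, stat: str) -> FeatureRatio:
    """Fruit-to-leaf ratio of one statistic (e.g. RSD_RGR / RSD_RPCR).

    Windows must match; a null or zero denominator propagates to a null ratio.
    """
    if fruit.window != leaf.window:
        raise ValidationError(
            f"window mismatch: {fruit.window.window_kind}@{fruit.window.date.date()} vs "
            f"{leaf.window.window_kind}@{leaf.window.date.date()}"
        )
    num = getattr(fruit, _STAT_ATTR[stat])
    den = getattr(leaf, _STAT_ATTR[stat])
    if num is None or den is None or np.isnan(num) or np.isnan(den) or den == 0:
        return FeatureRatio(stat, fruit.window, None)
    return FeatureRatio(stat, fruit.window, float(num / den))


_STAT_ATTR = {"rsd": "rsd", "max": "vmax", "min": "vmin", "sum": "vsum", "mean": "mean"}


def ratio_table(fruit_features: pd.DataFrame, leaf_features: pd.DataFrame, stats=("rsd", "max", "min", "sum")) -> pd.DataFrame:
    """Join fruit and leaf feature tables and form fruit/leaf ratios per stat."""
    merged = fruit_features.merge(
        leaf_features, on=["date", "window_kind"], suffixes=("_fruit", "_leaf")
    )
    out = merged[["date", "window_kind"]].copy()
    for stat in stats:
        num, den = merged[f"{stat}_fruit"], merged[f"{stat}_leaf"]
        out[f"{stat}_ratio"] = np.where(den.abs() > 0, num / den, np.nan)
    return out
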