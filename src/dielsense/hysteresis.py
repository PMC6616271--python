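"""Diel hysteresis loops between leaf and fruit rate signals.

The diel trajectory of RPCR plotted against RGR at 15-min steps traces a
closed loop whose rotational direction reflects the phase relationship of the
two organs' water flows (anticlockwise when the leaf signal leads the fruit
signal) and whose area grows with water deficit.  The loop is quantified by
the shoelace signed area of the closed ordered polygon; positive area is
anticlockwise by convention.  Self-intersecting trajectories (possible in
noisy data) receive the algebraic shoelace value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import RateSeries

ANTICLOCKWISE = "anticlockwise"
CLOCKWISE = "clockwise"
DEGENERATE = "degenerate"


@dataclass
class HysteresisLoop:
    """A closed diel trajectory in the (RGR, RPCR) plane."""

    day: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    timestamps: pd.DatetimeIndex
    signed_area: float
    direction: str
    closure_gap: float

    @property
    def n_points(self) -> int:
        return len(self.x)


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the polygon (x_i, y_i), closed last-to-first.

    Positive for anticlockwise vertex order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def build_loop(
    rgr: RateSeries | pd.Series,
    rpcr: RateSeries | pd.Series,
    day,
    anchor: str = "midnight",
    area_tol: float = 1e-12,
) -> HysteresisLoop:
    """Build the closed diel loop of RPCR (y) versus RGR (x) for one day.

    ``anchor`` selects the 24-h span: ``"midnight"`` (00:00 -> 23:45 of
    ``day``) or ``"morning"`` (07:00 of ``day`` -> 06:45 of the next day).
    Points present in both series (NaNs dropped pairwise) are connected in
    time order and the loop is closed from the last point back to the first.
    Fewer than three distinct points make the loop degenerate with zero area.
    """
    x_values = rgr.values if isinstance(rgr, RateSeries) else rgr
    y_values = rpcr.values if isinstance(rpcr, RateSeries) else rpcr
    day = pd.Timestamp(day).normalize()
    start = day if anchor == "midnight" else day + pd.Timedelta(hours=7)
    stop = start + pd.Timedelta(hours=24) - pd.Timedelta(minutes=15)
    frame = pd.concat({"x": x_values, "y": y_values}, axis=1).loc[start:stop].dropna()
    x = frame["x"].to_numpy()
    y = frame["y"].to_numpy()
    distinct = len(np.unique(np.column_stack([x, y]), axis=0)) if len(x) else 0
    if distinct < 3:
        return HysteresisLoop(day, x, y, frame.index, 0.0, DEGENERATE, 0.0)
    area = shoelace_area(x, y)
    closure = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return HysteresisLoop(day, x, y, frame.index, area, _direction(area, area_tol), closure)


def _direction(area: float, tol: float) -> str:
    if abs(area) <= tol:
        return DEGENERATE
    return ANTICLOCKWISE if area > 0 else CLOCKWISE


def loop_area(loop: HysteresisLoop) -> float:
    """Signed shoelace area of a loop (0 for degenerate loops)."""
    return loop.signed_area


def loop_direction(loop: HysteresisLoop, tol: float = 1e-12) -> str:
    """Rotational direction from the sign of the signed area."""
    if loop.direction == DEGENERATE:
        return DEGENERATE
    return _direction(loop.signed_area, tol)


def loop_metrics_table(loops: list[tuple[dict, HysteresisLoop]]) -> pd.DataFrame:
    """Tabulate loop metrics; each entry pairs provenance labels with a loop."""
    rows = []
    for labels, loop in loops:
        rows.append(
            {
                **labels,
                "day": loop.day.date(),
                "signed_area": loop.signed_area,
                "direction": loop.direction,
                "closure_gap": loop.closure_gap,
                "n_points": loop.n_points,
            }
        )
    return pd.DataFrame(rows)
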