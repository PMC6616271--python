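"""Plot helpers: diel hysteresis loops and fitted model curves.

Matplotlib is imported lazily so headless analysis runs never touch a
display backend.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_loop(loop, ax=None, **kwargs):
    """Draw one closed RPCR-vs-RGR diel loop with its direction annotated."""
    ax = _axes(ax)
    x = np.append(loop.x, loop.x[:1])
    y = np.append(loop.y, loop.y[:1])
    ax.plot(x, y, marker=".", markersize=3, **kwargs)
    ax.set_xlabel("RGR (per 15 min)")
    ax.set_ylabel("RPCR (per 15 min)")
    ax.set_title(f"{loop.day.date()}  area={loop.signed_area:.2e} ({loop.direction})")
    return ax


def plot_fit(results, ax=None, n_grid: int = 200, **kwargs):
    """Scatter the data behind a fitted rate model and overlay the curve."""
    ax = _axes(ax)
    model = results.model
    ax.scatter(model.x, model.y, s=12, alpha=0.7)
    grid = np.linspace(float(np.min(model.x)), float(np.max(model.x)), n_grid)
    ax.plot(grid, results.predict(grid), color="crimson", **kwargs)
    ax.set_xlabel("midday stem water potential (MPa)")
    ax.set_title(f"{model.form}: R^2 = {results.rsquared:.3f}")
    return ax
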