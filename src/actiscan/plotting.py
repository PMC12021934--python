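"""Curve plots of the 24-window association scan (Q5 vs Q1 with 95% CI)."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_curves(curve: pd.DataFrame, path, logistic: bool = True, title: str | None = None):
    """Plot a 24-point estimate curve with a CI ribbon.

    ``curve`` needs window_index, estimate, ci_low, ci_high (log-OR or beta
    scale) and optionally status; non-estimable windows are left as visible
    gaps, never interpolated. For logistic results the y axis is OR on a log
    scale. Empty input is a no-op with a warning.
    """
    if curve is None or len(curve) == 0:
        warnings.warn("plot_curves: empty curve input; nothing plotted")
        return None

    c = curve.sort_values("window_index").copy()
    if "status" in c.columns:
        bad = c["status"] != "ok"
        c.loc[bad, ["estimate", "ci_low", "ci_high"]] = np.nan

    fig, ax = plt.subplots(figsize=(8, 4))
    x = c["window_index"].to_numpy(dtype=float)
    if logistic:
        est, lo, hi = np.exp(c["estimate"]), np.exp(c["ci_low"]), np.exp(c["ci_high"])
        ax.set_yscale("log")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("OR (Q5 vs Q1)")
    else:
        est, lo, hi = c["estimate"], c["ci_low"], c["ci_high"]
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("beta (Q5 vs Q1)")
    ax.fill_between(x, lo, hi, alpha=0.25, step=None)
    ax.plot(x, est, marker="o", ms=3)
    ax.set_xlabel("hourly window (end of hour)")
    ax.set_xticks(range(1, 25, 2))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
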