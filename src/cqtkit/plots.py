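"""Report figures: time-course overlays, exposure-response, deciles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .diagnostics import decile_summary
from .model import CqtcFit, predict_ddqtcf


def plot_timecourse(rows, path, value_col="ddqtcf_ms", ylabel="ddQTcF (ms)"):
    """Mean time course of a derived quantity per treatment arm."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for trt, grp in rows.groupby("treatment"):
        course = grp.groupby("time_h")[value_col].mean()
        ax.plot(course.index, course.values, marker="o", label=str(trt))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("time post-dose (h)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loess_vs_linear(rows, path, span=0.75):
    """Observed exposure-response scatter with LOESS and linear overlays."""
    x = rows["conc"].to_numpy(float)
    y = rows["ddqtcf_ms"].to_numpy(float)
    grid = np.linspace(x.min(), x.max(), 100)
    slope, intercept = np.polyfit(x, y, 1)
    smooth = lowess(y, x, frac=span, xvals=grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, y, ".", ms=3, alpha=0.4, color="grey")
    ax.plot(grid, slope * grid + intercept, "-", label="linear")
    ax.plot(grid, smooth, "--", label=f"LOESS (span {span})")
    ax.set_xlabel("concentration (ng/mL)")
    ax.set_ylabel("ddQTcF (ms)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_model_with_deciles(rows, fit: CqtcFit, path, level=0.90):
    """Model-predicted mean ddQTcF with CI band and decile summaries."""
    pos = rows[rows["conc"] > 0]
    grid = np.linspace(0.0, pos["conc"].max(), 100)
    preds = [predict_ddqtcf(fit, c, level) for c in grid]
    mean = [p.mean_ms for p in preds]
    lo = [p.ci_lower_ms for p in preds]
    hi = [p.ci_upper_ms for p in preds]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(grid, lo, hi, alpha=0.25, label=f"{level:.0%} CI")
    ax.plot(grid, mean, "-", color="black", label="model mean")
    dec = decile_summary(rows, level)
    ax.errorbar(
        dec["conc_mean"], dec["ddqtcf_mean_ms"],
        yerr=[dec["ddqtcf_mean_ms"] - dec["ci_lower_ms"],
              dec["ci_upper_ms"] - dec["ddqtcf_mean_ms"]],
        fmt="o", color="purple", label="deciles",
    )
    ax.axhline(10.0, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("concentration (ng/mL)")
    ax.set_ylabel("ddQTcF (ms)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
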