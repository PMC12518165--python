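"""Pre-modeling assumption checks for the concentration-QTc analysis.

Four checks precede the mixed-model fit: (1) no meaningful drug effect on
heart rate (|mean ddHR| < 10 bpm at every timepoint), which justifies a fixed
heart-rate correction; (2) no hysteresis, i.e. the ddQTcF time course peaks
with (not after) the concentration time course; (3) linearity of the
exposure-response relationship, by comparing a LOESS smooth against the
simple linear regression; (4) no covariate-group effect on the dQTcF time
course. Hysteresis and linearity are inherently graphical judgements; here
they are made machine-checkable with documented, configurable thresholds
(peak lag > 1 h; max LOESS-vs-linear discrepancy > 0.5 residual SD), which
are artifact policy rather than regulatory constants. A decile summary of the
positive-concentration observations supports goodness-of-fit plots.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "HrCheck",
    "HysteresisCheck",
    "LinearityCheck",
    "GroupEffectCheck",
    "check_hr_effect",
    "check_hysteresis",
    "check_linearity",
    "check_group_effect",
    "decile_summary",
    "diagnostic_report",
]


@dataclass
class HrCheck:
    max_abs_mean_ddhr_bpm: float
    worst_time_h: float
    threshold_bpm: float
    passed: bool


@dataclass
class HysteresisCheck:
    t_peak_conc_h: float
    t_peak_ddqtcf_h: float
    lag_h: float
    lag_tolerance_h: float
    flagged: bool


@dataclass
class LinearityCheck:
    max_abs_discrepancy_ms: float
    residual_sd_ms: float
    flag_fraction: float
    flagged: bool


@dataclass
class GroupEffectCheck:
    max_abs_group_difference_ms: float
    scale_reference_ms: float
    flag_fraction: float
    flagged: bool


def check_hr_effect(rows: pd.DataFrame, threshold_bpm: float = 10.0) -> HrCheck:
    """Heart-rate gate: every timepoint's |mean ddHR| strictly below threshold.

    ``rows`` needs columns ``time_h`` and ``ddhr_bpm``; at least one timepoint
    must have two or more observations.
    """
    if rows.empty:
        raise ValueError("no ddHR observations supplied")
    counts = rows.groupby("time_h")["ddhr_bpm"].count()
    if not (counts >= 2).any():
        raise ValueError("no timepoint has at least 2 observations")
    means = rows.groupby("time_h")["ddhr_bpm"].mean()
    worst = means.abs().idxmax()
    max_abs = float(means.abs().max())
    return HrCheck(
        max_abs_mean_ddhr_bpm=max_abs,
        worst_time_h=float(worst),
        threshold_bpm=threshold_bpm,
        passed=bool(max_abs < threshold_bpm),
    )


def _earliest_peak(series: pd.Series) -> float:
    """Time of the maximum; ties broken to the earliest time (flat courses
    therefore peak at the first point)."""
    s = series.sort_index()
    return float(s.index[int(np.argmax(s.to_numpy()))])


def check_hysteresis(conc_by_time, ddqtcf_by_time,
                     lag_tolerance_h: float = 1.0) -> HysteresisCheck:
    """Compare peak times of the mean concentration and mean ddQTcF courses.

    Both inputs are mappings/Series indexed by nominal time; they must share
    at least 4 timepoints. A positive lag larger than the tolerance flags
    possible hysteresis (effect trailing exposure).
    """
    conc = pd.Series(conc_by_time, dtype=float)
    eff = pd.Series(ddqtcf_by_time, dtype=float)
    shared = conc.index.intersection(eff.index)
    if len(shared) < 4:
        raise ValueError("time courses share fewer than 4 nominal timepoints")
    t_conc = _earliest_peak(conc[shared])
    t_eff = _earliest_peak(eff[shared])
    lag = t_eff - t_conc
    return HysteresisCheck(
        t_peak_conc_h=t_conc,
        t_peak_ddqtcf_h=t_eff,
        lag_h=float(lag),
        lag_tolerance_h=lag_tolerance_h,
        flagged=bool(lag > lag_tolerance_h),
    )


def check_linearity(rows: pd.DataFrame, span: float = 0.75, n_grid: int = 50,
                    flag_fraction: float = 0.5) -> LinearityCheck:
    """LOESS-versus-linear discrepancy over the observed concentration range.

    Fits a local-linear LOESS (tricube weights, given span) and a simple
    linear regression of ddQTcF on concentration, and reports the maximum
    absolute discrepancy over an even grid; the check flags when it exceeds
    ``flag_fraction`` of the linear fit's residual SD. Invariant to affine
    rescaling of the concentration units.
    """
    if len(rows) < 20:
        raise ValueError("at least 20 observations are required")
    x = rows["conc"].to_numpy(dtype=float)
    y = rows["ddqtcf_ms"].to_numpy(dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("at least 5 distinct concentrations are required")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    resid_sd = float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1)))

    grid = np.linspace(x.min(), x.max(), n_grid)
    smooth = lowess(y, x, frac=span, xvals=grid)
    disc = float(np.max(np.abs(smooth - (slope * grid + intercept))))
    # floating-point floor so an exactly linear dataset never flags
    floor = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    return LinearityCheck(
        max_abs_discrepancy_ms=disc,
        residual_sd_ms=resid_sd,
        flag_fraction=flag_fraction,
        flagged=bool(disc > max(flag_fraction * resid_sd, floor)),
    )


def check_group_effect(adjusted: pd.DataFrame, group_col: str,
                       value_col: str = "dqtcf_ms",
                       flag_fraction: float = 0.5) -> GroupEffectCheck:
    """Covariate-impact check on group-mean time courses.

    Computes each group's mean time course of ``value_col`` and the maximum
    absolute between-group difference at any shared timepoint, referenced to
    the pooled within-group SD with the same 0.5-fraction rule as the
    linearity check. Used e.g. for challenge-vs-no-challenge or diet groups;
    a pass means no model covariate is needed.
    """
    if group_col not in adjusted.columns:
        raise ValueError(f"missing group column {group_col!r}")
    sub = adjusted[adjusted["time_h"] > 0]
    if sub[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups to compare")
    means = sub.groupby([group_col, "time_h"])[value_col].mean().unstack(group_col)
    means = means.dropna()  # shared timepoints only
    if means.empty:
        raise ValueError("groups share no timepoints")
    diff = float((means.max(axis=1) - means.min(axis=1)).max())
    pooled_sd = float(sub.groupby(group_col)[value_col].std(ddof=1).mean())
    return GroupEffectCheck(
        max_abs_group_difference_ms=diff,
        scale_reference_ms=pooled_sd,
        flag_fraction=flag_fraction,
        flagged=bool(diff > flag_fraction * pooled_sd),
    )


def decile_summary(rows: pd.DataFrame, level: float = 0.90) -> pd.DataFrame:
    """Decile table of the positive-concentration observations.

    Rows with ``conc > 0`` are ranked by concentration and split into 10
    near-equal groups (any remainder spread over the lowest groups); each
    group reports its mean concentration and the mean ddQTcF with a t-based
    two-sided CI at ``level``.
    """
    pos = rows[rows["conc"] > 0].sort_values("conc", kind="stable")
    n = len(pos)
    if n < 10:
        raise ValueError("at least 10 positive-concentration rows are required")
    base, rem = divmod(n, 10)
    sizes = [base + 1] * rem + [base] * (10 - rem)
    out = []
    start = 0
    for k, size in enumerate(sizes, start=1):
        grp = pos.iloc[start:start + size]
        start += size
        m = float(grp["ddqtcf_ms"].mean())
        sd = float(grp["ddqtcf_ms"].std(ddof=1)) if size > 1 else 0.0
        half = 0.0
        if size > 1 and sd > 0:
            half = stats.t.ppf(0.5 + level / 2.0, size - 1) * sd / np.sqrt(size)
        out.append({
            "decile": k,
            "n": size,
            "conc_mean": float(grp["conc"].mean()),
            "ddqtcf_mean_ms": m,
            "ci_lower_ms": m - half,
            "ci_upper_ms": m + half,
        })
    return pd.DataFrame(out)


def diagnostic_report(rows: pd.DataFrame, *, hr_threshold_bpm: float = 10.0,
                      lag_tolerance_h: float = 1.0, span: float = 0.75,
                      flag_fraction: float = 0.5, level: float = 0.90) -> dict:
    """Run every applicable check on a model-ready row table; JSON-friendly."""
    report: dict = {}
    if "ddhr_bpm" in rows.columns:
        report["hr_check"] = asdict(check_hr_effect(rows, hr_threshold_bpm))
    pos = rows[rows["conc"] > 0]
    if not pos.empty:
        conc_course = pos.groupby("time_h")["conc"].mean()
        eff_course = pos.groupby("time_h")["ddqtcf_ms"].mean()
        if len(conc_course) >= 4:
            report["hysteresis_check"] = asdict(
                check_hysteresis(conc_course, eff_course, lag_tolerance_h)
            )
    if len(rows) >= 20 and rows["conc"].nunique() >= 5:
        report["linearity_check"] = asdict(
            check_linearity(rows, span=span, flag_fraction=flag_fraction)
        )
    if len(pos) >= 10:
        report["decile_table"] = decile_summary(rows, level).to_dict("records")
    return report
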