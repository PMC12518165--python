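"""Non-compartmental pharmacokinetic analysis and geometric summaries.

AUC uses the linear-up/log-down trapezoid (logarithmic interpolation whenever
the concentration declines between two positive samples, which matches the
near-exponential decline of real profiles; plain trapezoid otherwise). The
terminal rate constant ``lambda_z`` comes from a log-linear regression over
the terminal window with the best adjusted R-squared among contiguous
candidate windows of >= 3 points strictly after tmax (ties to the longer
window); when no such window exists the last two positive samples are used,
including tmax if unavoidable. ``AUC_inf = AUC_last + C_last / lambda_z``;
``t_half = ln 2 / lambda_z``. A profile with no usable declining terminal
phase reports these as undefined, with the reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NcaResult",
    "nca_profile",
    "geometric_summary",
    "dose_proportionality",
    "nca_by_subject",
]


@dataclass
class NcaResult:
    cmax: float
    tmax_h: float
    auc_last: float
    auc_inf: float | None
    lambda_z: float | None
    t_half_h: float | None
    n_lambda_points: int
    extrapolated_fraction: float | None
    lambda_z_reason: str | None = None  # why lambda_z is undefined, if it is


def _auc_linup_logdown(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def _loglin_slope(t: np.ndarray, c: np.ndarray):
    """Slope and adjusted R^2 of ln(c) on t."""
    ln = np.log(c)
    slope, intercept = np.polyfit(t, ln, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((ln - fitted) ** 2))
    ss_tot = float(np.sum((ln - ln.mean()) ** 2))
    m = len(t)
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
    return float(slope), float(adj)


def nca_profile(times_h, concs) -> NcaResult:
    """Non-compartmental parameters for one concentration-time profile.

    ``times_h`` must be strictly increasing and ``concs`` non-negative, with
    at least 3 samples and at least one positive concentration.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times_h and concs must be 1-D of equal length")
    if len(t) < 3:
        raise ValueError("at least 3 samples are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_h must be strictly increasing")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("concs must be non-negative and finite")
    if not np.any(c > 0):
        raise ValueError("profile has no positive concentrations")

    i_max = int(np.argmax(c))  # argmax returns the earliest maximum
    cmax = float(c[i_max])
    tmax = float(t[i_max])

    i_last = int(np.max(np.nonzero(c > 0)))
    auc_last = _auc_linup_logdown(t[: i_last + 1], c[: i_last + 1])
    c_last = float(c[i_last])

    # terminal window: positive concentrations strictly after tmax
    term = [i for i in range(i_max + 1, i_last + 1) if c[i] > 0]
    best = None  # (adj_r2, n_points, slope)
    decline = -1e-12  # a numerically flat profile has no terminal phase
    if len(term) >= 3:
        for start in range(0, len(term) - 2):  # longest window first
            win = term[start:]
            slope, adj = _loglin_slope(t[win], c[win])
            if slope >= decline:
                continue
            if best is None or adj > best[0]:  # ties keep the longer window
                best = (adj, len(win), slope)
    elif len(term) >= 1:
        # fallback: last two positive samples, tmax included if unavoidable
        win = ([i_max] + term)[-2:]
        if len(win) == 2:
            slope, adj = _loglin_slope(t[win], c[win])
            if slope < decline:
                best = (adj, 2, slope)

    if best is None:
        reason = "no declining terminal phase for lambda_z"
        return NcaResult(cmax, tmax, auc_last, None, None, None, 0, None, reason)

    _, n_pts, slope = best
    lz = -slope
    auc_inf = auc_last + c_last / lz
    return NcaResult(
        cmax=cmax,
        tmax_h=tmax,
        auc_last=auc_last,
        auc_inf=float(auc_inf),
        lambda_z=float(lz),
        t_half_h=float(np.log(2.0) / lz),
        n_lambda_points=int(n_pts),
        extrapolated_fraction=float((auc_inf - auc_last) / auc_inf),
    )


def geometric_summary(values) -> dict:
    """Geometric mean and geometric CV% of strictly positive values.

    ``gmean = exp(mean(ln v))``; ``gCV% = 100 sqrt(exp(s^2) - 1)`` with ``s``
    the (n-1)-denominator SD of ``ln v``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("at least 2 values are required")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("values must be strictly positive and finite")
    ln = np.log(v)
    s = float(np.std(ln, ddof=1))
    return {
        "gmean": float(np.exp(ln.mean())),
        "gcv_percent": float(100.0 * np.sqrt(np.expm1(s**2))),
    }


def dose_proportionality(summaries_by_dose: dict, band=(0.8, 1.25)) -> pd.DataFrame:
    """Dose-normalized geometric-mean ratios relative to the lowest dose.

    ``summaries_by_dose`` maps dose (mg) to a dict with ``cmax`` and
    ``auc_inf`` geometric means. Ratios outside ``band`` are flagged.
    """
    if len(summaries_by_dose) < 2:
        raise ValueError("at least 2 dose levels are required")
    doses = sorted(summaries_by_dose)
    ref = doses[0]
    rows = []
    for dose in doses[1:]:
        for param in ("cmax", "auc_inf"):
            try:
                num = summaries_by_dose[dose][param] / dose
                den = summaries_by_dose[ref][param] / ref
            except KeyError as exc:
                raise ValueError(f"missing {param} for dose {dose} or {ref}") from exc
            ratio = num / den
            rows.append({
                "dose_mg": dose,
                "reference_dose_mg": ref,
                "parameter": param,
                "normalized_ratio": float(ratio),
                "flagged": bool(not band[0] <= ratio <= band[1]),
            })
    return pd.DataFrame(rows)


def nca_by_subject(pk: pd.DataFrame) -> pd.DataFrame:
    """Per subject x treatment NCA over post-dose samples of a PK table."""
    out = []
    for (sid, trt), grp in pk[pk["time_h"] > 0].groupby(["subject_id", "treatment"]):
        grp = grp.sort_values("time_h")
        res = nca_profile(grp["time_h"].to_numpy(), grp["conc"].to_numpy())
        rec = {"subject_id": sid, "treatment": trt}
        rec.update(vars(res))
        out.append(rec)
    return pd.DataFrame(out)
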