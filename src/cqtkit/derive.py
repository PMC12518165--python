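"""Derivation of model-ready observations from raw ECG intervals.

The chain is: heart rate and Fridericia-corrected QT (QTcF) from the measured
QT/RR intervals; baseline adjustment within subject x period (dQTcF = change
from the pre-dose baseline); placebo correction to the drug-attributable
ddQTcF, either with each subject's own time-matched placebo period (crossover)
or against the pooled placebo-arm mean (parallel design); and finally pairing
with the time-matched plasma concentration. Heart rate runs through the
identical adjust/correct chain, yielding dHR and ddHR for the diagnostics.

Every dropping step is counted: the number of model-ready rows plus the number
of dropped rows always equals the number of eligible active-arm records.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import PLACEBO, analyte_for_treatment

log = logging.getLogger(__name__)

#: Columns of a model-ready observation table.
CQT_ROW_COLUMNS = (
    "subject_id",
    "treatment",
    "period",
    "day",
    "time_h",
    "conc",
    "ddqtcf_ms",
    "ddhr_bpm",
    "baseline_qtcf_ms",
)


def heart_rate(rr_ms):
    """Heart rate in beats/min from the RR interval in ms (HR = 60/RR[s])."""
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
        raise ValueError("rr_ms must be positive and finite")
    out = 60.0 / (rr / 1000.0)
    return float(out) if np.isscalar(rr_ms) else out


def fridericia(qt_ms, rr_ms):
    """Fridericia-corrected QT: QTcF = QT / (RR/1000)^(1/3), intervals in ms.

    At RR = 1000 ms (60 bpm) the correction is the identity.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("qt_ms and rr_ms must be positive")
    out = qt / np.cbrt(rr / 1000.0)
    return float(out) if np.isscalar(qt_ms) and np.isscalar(rr_ms) else out


def derive_intervals(ecg: pd.DataFrame) -> pd.DataFrame:
    """Add ``hr_bpm`` and ``qtcf_ms`` columns to an ECG interval table."""
    out = ecg.copy()
    out["hr_bpm"] = heart_rate(out["rr_ms"].to_numpy())
    out["qtcf_ms"] = fridericia(out["qt_ms"].to_numpy(), out["rr_ms"].to_numpy())
    return out


def baseline_adjust(derived: pd.DataFrame, baseline_rule: str = "day1") -> pd.DataFrame:
    """Baseline-adjust QTcF and HR within each subject x treatment x period.

    The baseline is the arithmetic mean of the pre-dose (``time_h <= 0``)
    replicates; ``dqtcf_ms = qtcf_ms - baseline_qtcf_ms`` and likewise
    ``dhr_bpm``. With ``baseline_rule="day1"`` (default) the Day-1 pre-dose
    baseline applies to all days of the period; with ``"per_day"`` each day
    uses its own pre-dose records. Groups without a baseline are excluded with
    a logged warning.
    """
    if baseline_rule not in ("day1", "per_day"):
        raise ValueError(f"unknown baseline_rule {baseline_rule!r}")
    group_cols = ["subject_id", "treatment", "period"]
    if baseline_rule == "per_day":
        group_cols = group_cols + ["day"]

    pre = derived[derived["time_h"] <= 0]
    if baseline_rule == "day1":
        pre = pre[pre["day"] == 1]
    base = (
        pre.groupby(group_cols)
        .agg(baseline_qtcf_ms=("qtcf_ms", "mean"), baseline_hr_bpm=("hr_bpm", "mean"))
        .reset_index()
    )

    out = derived.merge(base, on=group_cols, how="left")
    missing = out["baseline_qtcf_ms"].isna()
    if missing.any():
        dropped = out.loc[missing, group_cols].drop_duplicates()
        for _, row in dropped.iterrows():
            log.warning(
                "no pre-dose baseline for %s; excluding its records",
                tuple(row.values),
            )
        out = out[~missing].copy()
    out["dqtcf_ms"] = out["qtcf_ms"] - out["baseline_qtcf_ms"]
    out["dhr_bpm"] = out["hr_bpm"] - out["baseline_hr_bpm"]
    return out.reset_index(drop=True)


_MATCH_COLS = ["subject_id", "day", "time_h"]


def placebo_correct_crossover(adjusted: pd.DataFrame):
    """Placebo-correct with each subject's own time-matched placebo period.

    For every subject, active arm (any non-placebo treatment), and nominal
    time: ``ddqtcf = dqtcf(active) - dqtcf(placebo at the same nominal time)``.
    Active rows without a matching placebo record are dropped and counted;
    subjects without a placebo period lose all rows, with a warning.

    Returns ``(rows, accounting)`` where ``accounting`` reconciles input
    active-arm rows with output rows plus drops.
    """
    post = adjusted[adjusted["time_h"] > 0]
    plac = post[post["treatment"] == PLACEBO]
    act = post[post["treatment"] != PLACEBO]

    no_placebo = sorted(set(act["subject_id"]) - set(plac["subject_id"]))
    for sid in no_placebo:
        log.warning("subject %s has no placebo period; dropping its rows", sid)

    ref = plac[_MATCH_COLS + ["dqtcf_ms", "dhr_bpm"]].rename(
        columns={"dqtcf_ms": "dqtcf_placebo", "dhr_bpm": "dhr_placebo"}
    )
    merged = act.merge(ref, on=_MATCH_COLS, how="left")
    matched = merged["dqtcf_placebo"].notna()
    rows = merged[matched].copy()
    rows["ddqtcf_ms"] = rows["dqtcf_ms"] - rows["dqtcf_placebo"]
    rows["ddhr_bpm"] = rows["dhr_bpm"] - rows["dhr_placebo"]
    accounting = {
        "n_active_rows": int(len(act)),
        "n_rows": int(len(rows)),
        "n_dropped_no_placebo_match": int((~matched).sum()),
        "subjects_without_placebo": no_placebo,
    }
    keep = [c for c in rows.columns if not c.endswith("_placebo")]
    return rows[keep].reset_index(drop=True), accounting


def placebo_correct_parallel(adjusted: pd.DataFrame, match_cols=("day", "time_h")):
    """Placebo-correct against the pooled placebo-arm mean (parallel design).

    Each active-arm record's ``ddqtcf`` is its ``dqtcf`` minus the mean
    ``dqtcf`` of all placebo subjects at the same day and nominal time (pass
    ``match_cols=("cohort", "day", "time_h")`` for per-cohort matching).
    """
    match_cols = list(match_cols)
    post = adjusted[adjusted["time_h"] > 0]
    plac = post[post["treatment"] == PLACEBO]
    if plac.empty:
        raise ValueError("parallel-design correction requires a non-empty placebo arm")
    act = post[post["treatment"] != PLACEBO]

    ref = (
        plac.groupby(match_cols)
        .agg(dqtcf_placebo=("dqtcf_ms", "mean"), dhr_placebo=("dhr_bpm", "mean"))
        .reset_index()
    )
    merged = act.merge(ref, on=match_cols, how="left")
    matched = merged["dqtcf_placebo"].notna()
    if (~matched).any():
        log.warning(
            "%d active rows had no placebo records at a matched time",
            int((~matched).sum()),
        )
    rows = merged[matched].copy()
    rows["ddqtcf_ms"] = rows["dqtcf_ms"] - rows["dqtcf_placebo"]
    rows["ddhr_bpm"] = rows["dhr_bpm"] - rows["dhr_placebo"]
    accounting = {
        "n_active_rows": int(len(act)),
        "n_rows": int(len(rows)),
        "n_dropped_no_placebo_match": int((~matched).sum()),
        "subjects_without_placebo": [],
    }
    keep = [c for c in rows.columns if not c.endswith("_placebo")]
    return rows[keep].reset_index(drop=True), accounting


def pair_concentration(rows: pd.DataFrame, pk: pd.DataFrame):
    """Attach the same-subject, same-arm, time-matched concentration to rows.

    Matching is exact on (subject, treatment, period, day, nominal time), with
    the analyte implied by the arm (moxifloxacin arm pairs with the
    moxifloxacin analyte, drug arms with the drug analyte). Pre-dose rows
    carry concentration 0 by definition; unmatched post-dose rows are dropped
    and counted.
    """
    conc = pk.rename(columns={"analyte": "_analyte"})[
        ["subject_id", "period", "day", "time_h", "_analyte", "conc"]
    ]
    out = rows.copy()
    out["_analyte"] = out["treatment"].map(analyte_for_treatment)
    merged = out.merge(
        conc, on=["subject_id", "period", "day", "time_h", "_analyte"], how="left"
    )
    predose = merged["time_h"] <= 0
    merged.loc[predose, "conc"] = merged.loc[predose, "conc"].fillna(0.0)
    matched = merged["conc"].notna()
    n_dropped = int((~matched).sum())
    if n_dropped:
        log.warning("%d rows had no time-matched concentration; dropped", n_dropped)
    paired = merged[matched].drop(columns=["_analyte"]).reset_index(drop=True)
    accounting = {"n_rows_in": int(len(rows)), "n_rows": int(len(paired)),
                  "n_dropped_no_conc_match": n_dropped}
    return paired, accounting
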