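"""Domain tables, CSV I/O, and validation shared by every pipeline stage.

Datasets are long-format :class:`pandas.DataFrame` objects with fixed column
dialects (comma-separated, UTF-8, one header row):

* ECG intervals: ``subject_id, treatment, period, day, time_h, qt_ms, rr_ms``
* PK concentrations: ``subject_id, treatment, period, time_h, analyte, conc``
  plus optional ``day`` (defaults to 1) and ``lloq_flag`` columns.

Units are fixed: intervals in milliseconds, concentrations in ng/mL, nominal
times in hours relative to that day's dose (pre-dose rows carry
``time_h <= 0``). Readers never silently drop a row: every input row is either
accepted or returned in a rejection report with a reason, so that
``rows in == accepted + rejected`` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Treatment label of the placebo arm.
PLACEBO = "placebo"
#: Treatment label of the positive-control arm.
MOXIFLOXACIN = "moxifloxacin"

#: Analyte labels in PK files.
ANALYTE_DRUG = "drug"
ANALYTE_MOXIFLOXACIN = "moxifloxacin"

ECG_COLUMNS = ("subject_id", "treatment", "period", "day", "time_h", "qt_ms", "rr_ms")
PK_COLUMNS = ("subject_id", "treatment", "period", "time_h", "analyte", "conc")

#: Key columns under which ECG records must be unique.
ECG_KEY = ["subject_id", "treatment", "period", "day", "time_h"]
PK_KEY = ["subject_id", "treatment", "period", "day", "time_h", "analyte"]

DESIGN_CROSSOVER = "crossover"
DESIGN_PARALLEL = "parallel"


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


def is_placebo(treatment) -> bool:
    return treatment == PLACEBO


def is_active(treatment) -> bool:
    """True for any non-placebo arm (drug doses and the positive control)."""
    return treatment != PLACEBO


def is_drug_arm(treatment) -> bool:
    """True for study-drug dose arms (excludes placebo and moxifloxacin)."""
    return treatment not in (PLACEBO, MOXIFLOXACIN)


def analyte_for_treatment(treatment) -> str:
    """The PK analyte measured in a given active arm."""
    return ANALYTE_MOXIFLOXACIN if treatment == MOXIFLOXACIN else ANALYTE_DRUG


@dataclass(frozen=True)
class EcgRecord:
    """One measured ECG timepoint."""

    subject_id: str
    treatment: str
    period: int
    day: int
    time_h: float
    qt_ms: float
    rr_ms: float

    def is_physiological(self) -> bool:
        return 0 < self.qt_ms < self.rr_ms


@dataclass(frozen=True)
class ConcRecord:
    """One PK plasma sample."""

    subject_id: str
    treatment: str
    period: int
    day: int
    time_h: float
    analyte: str
    conc: float
    lloq_flag: bool = False


@dataclass
class Dataset:
    """A paired ECG + PK dataset with its design descriptor.

    The design descriptor (``"crossover"`` or ``"parallel"``) determines which
    placebo-correction operation is legal downstream.
    """

    ecg: pd.DataFrame
    pk: pd.DataFrame
    design: str = DESIGN_CROSSOVER

    def __post_init__(self):
        if self.design not in (DESIGN_CROSSOVER, DESIGN_PARALLEL):
            raise ValueError(f"unknown design {self.design!r}")


def _require_columns(df: pd.DataFrame, required, kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{kind} file is missing required column(s): {', '.join(missing)}"
        )


def _parse_table(raw, int_cols, float_cols, key, extra_checks):
    """Split raw string rows into typed accepted rows and a rejection report."""
    reasons = pd.Series("", index=raw.index, dtype=object)

    parsed = raw.copy()
    for col in int_cols:
        num = pd.to_numeric(parsed[col], errors="coerce")
        bad = num.isna() | (num != num.round())
        reasons[bad & (reasons == "")] = f"non-numeric {col}"
        parsed[col] = num
    for col in float_cols:
        num = pd.to_numeric(parsed[col], errors="coerce")
        reasons[num.isna() & (reasons == "")] = f"non-numeric {col}"
        parsed[col] = num

    for mask, reason in extra_checks(parsed):
        reasons[mask & (reasons == "")] = reason

    dup = parsed.duplicated(subset=key, keep="first") & (reasons == "")
    reasons[dup] = "duplicate key"

    ok = reasons == ""
    accepted = parsed[ok].copy()
    for col in int_cols:
        accepted[col] = accepted[col].astype(int)
    for col in float_cols:
        accepted[col] = accepted[col].astype(float)
    rejected = raw[~ok].copy()
    rejected["reason"] = reasons[~ok]
    return accepted.reset_index(drop=True), rejected.reset_index(drop=True)


def read_ecg_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an ECG interval CSV.

    Returns ``(accepted, rejected)``. Accepted rows are typed; physiologically
    implausible but parseable rows (``qt_ms >= rr_ms``) are kept and flagged in
    the boolean ``qt_ge_rr_flag`` column rather than dropped. Rejected rows
    keep their original text plus a ``reason`` column.

    Raises
    ------
    FormatError
        If a required column is absent.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, ECG_COLUMNS, "ECG")

    def checks(df):
        yield df["qt_ms"] <= 0, "non-positive qt_ms"
        yield df["rr_ms"] <= 0, "non-positive rr_ms"
        yield df["period"] < 1, "invalid period"
        yield df["day"] < 1, "invalid day"

    accepted, rejected = _parse_table(
        raw,
        int_cols=["period", "day"],
        float_cols=["time_h", "qt_ms", "rr_ms"],
        key=ECG_KEY,
        extra_checks=checks,
    )
    accepted["qt_ge_rr_flag"] = accepted["qt_ms"] >= accepted["rr_ms"]
    n_flag = int(accepted["qt_ge_rr_flag"].sum())
    if n_flag:
        log.warning("%d ECG record(s) flagged with qt_ms >= rr_ms", n_flag)
    return accepted, rejected


def read_pk_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a PK concentration CSV; see :func:`read_ecg_csv` for the contract.

    The optional ``day`` column defaults to 1 and ``lloq_flag`` to False.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, PK_COLUMNS, "PK")
    if "day" not in raw.columns:
        raw["day"] = "1"
    if "lloq_flag" not in raw.columns:
        raw["lloq_flag"] = "False"

    def checks(df):
        yield df["conc"] < 0, "negative conc"
        yield df["period"] < 1, "invalid period"
        yield df["day"] < 1, "invalid day"

    accepted, rejected = _parse_table(
        raw,
        int_cols=["period", "day"],
        float_cols=["time_h", "conc"],
        key=PK_KEY,
        extra_checks=checks,
    )
    accepted["lloq_flag"] = (
        accepted["lloq_flag"].astype(str).str.lower().isin(["true", "1", "yes"])
    )
    return accepted, rejected


def write_ecg_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df, ECG_COLUMNS, "ECG")
    df.to_csv(path, index=False)


def write_pk_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df, PK_COLUMNS, "PK")
    df.to_csv(path, index=False)


def write_rejections_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def apply_lloq(pk: pd.DataFrame, lloq: float) -> pd.DataFrame:
    """Apply lower-limit-of-quantification handling to PK records.

    Concentrations below ``lloq`` are set to 0 and flagged via ``lloq_flag``;
    values at or above ``lloq`` are untouched.

    Raises
    ------
    ValueError
        If ``lloq`` is not strictly positive.
    """
    if not np.isfinite(lloq) or lloq <= 0:
        raise ValueError(f"lloq must be positive, got {lloq}")
    out = pk.copy()
    below = out["conc"] < lloq
    out.loc[below, "lloq_flag"] = True
    out.loc[below, "conc"] = 0.0
    return out
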