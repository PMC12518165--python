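"""End-to-end analysis: derive -> placebo-correct -> pair -> fit -> verdicts.

This is the programmatic counterpart of the command-line ``analyze`` step and
the engine behind the simulation-based validation studies. Given long-format
ECG and PK tables it produces the model-ready observation rows, the
concentration-QTc fits for the study drug and (when present) the
moxifloxacin positive control, diagnostics, and the regulatory verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import derive
from .data import DESIGN_CROSSOVER, DESIGN_PARALLEL, MOXIFLOXACIN, PLACEBO
from .diagnostics import diagnostic_report
from .model import (
    CqtcFit,
    Prediction,
    Verdict,
    assess_assay_sensitivity,
    assess_no_prolongation,
    fit_cqtc,
    predict_ddqtcf,
)
from .nca import geometric_summary, nca_by_subject


@dataclass
class AnalysisResult:
    rows: pd.DataFrame                     # model-ready observations, all arms
    drug_fit: CqtcFit
    moxi_fit: CqtcFit | None
    predictions: list[Prediction]
    verdicts: list[Verdict]
    diagnostics: dict
    gmean_cmax: dict                       # treatment -> geometric mean Cmax
    accounting: dict = field(default_factory=dict)


def derive_model_rows(ecg: pd.DataFrame, pk: pd.DataFrame, design: str,
                      baseline_rule: str = "day1"):
    """Run the derivation chain and return ``(rows, accounting)``.

    ``rows`` covers every active arm (study drug and positive control), with
    the arm-appropriate analyte concentration attached.
    """
    derived = derive.derive_intervals(ecg)
    adjusted = derive.baseline_adjust(derived, baseline_rule=baseline_rule)
    if design == DESIGN_CROSSOVER:
        corrected, acct = derive.placebo_correct_crossover(adjusted)
    elif design == DESIGN_PARALLEL:
        corrected, acct = derive.placebo_correct_parallel(adjusted)
    else:
        raise ValueError(f"unknown design {design!r}")
    rows, pair_acct = derive.pair_concentration(corrected, pk)
    acct.update(pair_acct)
    return rows, acct


def analyze(ecg: pd.DataFrame, pk: pd.DataFrame, design: str = DESIGN_CROSSOVER,
            *, baseline_rule: str = "day1", conc_of_interest: float | None = None,
            level: float = 0.90, threshold_ms: float = 10.0,
            sensitivity_threshold_ms: float = 5.0) -> AnalysisResult:
    """Full concentration-QTc analysis of one study.

    Predictions and verdicts are evaluated at the concentration of interest
    (when given) and at each dose's observed geometric mean Cmax; the
    assay-sensitivity verdict is read at the positive control's geometric
    mean Cmax when a moxifloxacin arm is present.
    """
    rows, acct = derive_model_rows(ecg, pk, design, baseline_rule)
    if rows.empty:
        raise ValueError(
            f"derivation produced 0 model-ready rows (accounting: {acct})"
        )
    drug_rows = rows[rows["treatment"] != MOXIFLOXACIN]
    moxi_rows = rows[rows["treatment"] == MOXIFLOXACIN]

    drug_fit = fit_cqtc(drug_rows, level=level)
    moxi_fit = fit_cqtc(moxi_rows, level=level) if len(moxi_rows) else None

    # observed geometric mean Cmax per arm, from per-subject NCA
    nca = nca_by_subject(pk)
    gmean_cmax = {}
    for trt, grp in nca.groupby("treatment"):
        if trt != PLACEBO and len(grp) >= 2:
            gmean_cmax[trt] = geometric_summary(grp["cmax"])["gmean"]

    predictions: list[Prediction] = []
    verdicts: list[Verdict] = []
    eval_concs = []
    if conc_of_interest is not None:
        eval_concs.append(conc_of_interest)
    eval_concs += [c for t, c in sorted(gmean_cmax.items()) if t != MOXIFLOXACIN]
    for c in eval_concs:
        predictions.append(predict_ddqtcf(drug_fit, c, level))
        verdicts.append(assess_no_prolongation(drug_fit, c, threshold_ms, level))
    if moxi_fit is not None and MOXIFLOXACIN in gmean_cmax:
        cmax_moxi = gmean_cmax[MOXIFLOXACIN]
        predictions.append(predict_ddqtcf(moxi_fit, cmax_moxi, level))
        verdicts.append(assess_assay_sensitivity(
            moxi_fit, cmax_moxi, sensitivity_threshold_ms, level))

    diagnostics = diagnostic_report(drug_rows, level=level)
    return AnalysisResult(
        rows=rows, drug_fit=drug_fit, moxi_fit=moxi_fit,
        predictions=predictions, verdicts=verdicts, diagnostics=diagnostics,
        gmean_cmax=gmean_cmax, accounting=acct,
    )


def render_report(result: AnalysisResult) -> str:
    """Human-readable text report with model-estimate and verdict rows."""
    lines = ["Concentration-QTcF analysis", "=" * 28, ""]
    fit = result.drug_fit
    lines.append("Model: ddQTcF ~ (th0+eta0) + (th1+eta1)*C + th2*(B - Bbar)")
    lines.append(f"  subjects: {fit.n_subjects}   observations: {fit.n_obs}")
    lines.append(f"  Intercept th0 [ms]:            {fit.theta0: .4f}")
    lines.append(f"  Slope th1 [ms per ng/mL]:      {fit.theta1: .4f}")
    if fit.theta2 is not None:
        lines.append(f"  Centred baseline QTcF [ms/ms]: {fit.theta2: .4f}")
    lines.append("")
    for pred in result.predictions:
        lines.append(
            f"  Mean ddQTcF ({pred.level:.0%} CI) at {pred.conc:g} ng/mL: "
            f"{pred.mean_ms:.1f} ({pred.ci_lower_ms:.1f}, {pred.ci_upper_ms:.1f})"
        )
    lines.append("")
    for v in result.verdicts:
        word = "PASS" if v.passed else "FAIL"
        op = "<" if v.kind == "no_prolongation" else ">"
        lines.append(
            f"  [{word}] {v.kind} at {v.conc:g} ng/mL: bound "
            f"{v.bound_ms:.1f} ms {op} {v.threshold_ms:g} ms"
        )
    if result.moxi_fit is not None:
        m = result.moxi_fit
        lines += ["", "Positive control (moxifloxacin) model:",
                  f"  Intercept th0 [ms]:            {m.theta0: .4f}",
                  f"  Slope th1 [ms per ng/mL]:      {m.theta1: .4f}"]
    lines.append("")
    return "\n".join(lines)
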