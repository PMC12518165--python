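"""Synthetic thorough-QT and multiple-ascending-dose study generator.

Simulates the two study designs the pipeline targets, with known ground truth
so every downstream stage (derivation, correction, model fit, diagnostics,
NCA) is testable without access-controlled clinical data:

* ``crossover4x4``: a 4-period crossover thorough-QT study (default n = 28,
  Williams-square sequences, arms = two study-drug doses, placebo, and a
  moxifloxacin 400 mg positive control; single dose per period, dense 0.5-48 h
  sampling).
* ``parallel_mad``: a parallel-group multiple-ascending-dose study (default
  five 3:1 active:placebo cohorts, once-daily dosing for 10 days, ECG/PK days
  1 and 10).

Pharmacokinetics follow a two-compartment model with first-order oral
absorption (closed-form three-exponential solution; ``q = 0`` recovers the
one-compartment limit), log-normal inter-individual variability on CL/F and
V1, and once-daily superposition in MAD mode. QTcF is generated as::

    QTcF(t) = B_i + diurnal(clock(t)) + theta0 1{active, post-dose}
              + eta0_i 1{active, post-dose} + (theta1 + eta1_i) C(t) + eps

with a subject baseline ``B_i``, a two-harmonic (24 h + 12 h) cosine diurnal
rhythm shared across arms (so time-matched placebo correction cancels it
exactly), subject random intercept/slope ``(eta0, eta1) ~ N(0, Omega)``, and
residual noise. QT is back-computed from QTcF through the inverse Fridericia
transform using a simulated RR, so re-derivation through the pipeline
recovers the generated QTcF to numerical precision.

All randomness flows from a single seed via per-subject substreams; the same
config therefore reproduces bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .data import MOXIFLOXACIN, PLACEBO, ANALYTE_DRUG, ANALYTE_MOXIFLOXACIN

__all__ = [
    "PkParams",
    "QtcParams",
    "MoxiParams",
    "CohortSpec",
    "StudyConfig",
    "SimulatedStudy",
    "two_compartment_oral",
    "simulate_pk_profile",
    "accumulation_ratio",
    "simulate_study",
    "tqt_reference",
    "mad_reference",
]

#: Williams-square treatment sequences for the 4x4 crossover (A/B = low/high
#: dose, C = placebo, D = moxifloxacin).
WILLIAMS_4X4 = (
    ("A", "B", "C", "D"),
    ("B", "D", "A", "C"),
    ("C", "A", "D", "B"),
    ("D", "C", "B", "A"),
)


class PkParams(BaseModel):
    """Two-compartment oral PK parameters (typical values).

    Defaults are calibrated so that, with inter-individual variability, the
    simulated single-dose exposure matches the intended profile of a slowly
    eliminated drug: CL/F 3 L/h, biphasic decline with terminal half-life
    near 29 h, tmax within 0.5-4 h.
    """

    ka: float = 1.2            # absorption rate, 1/h
    cl_f: float = 3.0          # apparent clearance, L/h
    v1: float = 58.0           # central volume, L
    v2: float = 45.0           # peripheral volume, L
    q: float = 6.0             # inter-compartmental clearance, L/h (0 = 1-cmt)
    iiv_cv_percent: dict[str, float] = Field(
        default_factory=lambda: {"cl_f": 25.0, "v1": 25.0, "ka": 25.0}
    )

    @field_validator("ka", "cl_f", "v1")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("PK parameters must be positive")
        return v

    @field_validator("v2", "q")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("v2 and q must be non-negative")
        return v


class QtcParams(BaseModel):
    """QTcF generation parameters."""

    baseline_mean_ms: float = 412.0
    baseline_sd_ms: float = 12.0
    diurnal_amplitudes_ms: tuple[float, float] = (5.0, 2.0)  # 24 h, 12 h harmonics
    diurnal_phases_h: tuple[float, float] = (3.0, 9.0)
    dosing_clock_h: float = 8.0       # clock time of dosing
    theta0_ms: float = 0.0            # fixed treatment offset on active arms
    slope_ms_per_ng_ml: float = 0.0054
    omega: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 0.0), (0.0, 4e-6))
    residual_sd_ms: float = 6.0
    n_baseline_replicates: int = 3
    rr_mean_ms: float = 900.0
    rr_sd_ms: float = 30.0

    @field_validator("baseline_sd_ms", "residual_sd_ms", "rr_sd_ms")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("standard deviations must be non-negative")
        return v

    @model_validator(mode="after")
    def _omega_psd(self):
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2) or not np.allclose(om, om.T):
            raise ValueError("omega must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(om) < -1e-12):
            raise ValueError("omega must be positive semi-definite")
        return self


class MoxiParams(BaseModel):
    """Positive-control arm: one-compartment-limit PK and its QTc effect."""

    pk: PkParams = Field(
        default_factory=lambda: PkParams(ka=2.5, cl_f=8.9, v1=154.0, v2=1.0, q=0.0)
    )
    dose_mg: float = 400.0
    slope_ms_per_ng_ml: float = 0.0044
    theta0_ms: float = 2.6


class CohortSpec(BaseModel):
    dose_mg: float
    n_active: int
    n_placebo: int


#: Default MAD cohorts: five dose groups randomized 3:1 active:placebo.
DEFAULT_MAD_COHORTS = (
    CohortSpec(dose_mg=2.5, n_active=9, n_placebo=3),
    CohortSpec(dose_mg=5.0, n_active=9, n_placebo=3),
    CohortSpec(dose_mg=1.5, n_active=9, n_placebo=3),
    CohortSpec(dose_mg=2.5, n_active=6, n_placebo=2),
    CohortSpec(dose_mg=0.5, n_active=9, n_placebo=3),
)


class StudyConfig(BaseModel):
    """Full simulator specification; defaults reproduce the TQT conditions."""

    design: str = "crossover4x4"
    n_subjects: int = 28
    sequences: tuple[tuple[str, ...], ...] = WILLIAMS_4X4
    doses_mg: tuple[float, ...] = (16.0, 32.0)
    sampling_times_h: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0,
                                           6.0, 8.0, 12.0, 24.0, 48.0)
    predose_times_h: tuple[float, ...] = (-0.3, -0.2, -0.1)
    pk: PkParams = Field(default_factory=PkParams)
    qtc: QtcParams = Field(default_factory=QtcParams)
    moxifloxacin: MoxiParams | None = Field(default_factory=MoxiParams)
    cohorts: tuple[CohortSpec, ...] = DEFAULT_MAD_COHORTS
    n_days: int = 1
    ecg_days: tuple[int, ...] = (1,)
    hr_effect_bpm: float = 0.0
    hr_effect_days: tuple[int, ...] | None = None
    seed: int = 0

    @field_validator("design")
    @classmethod
    def _design(cls, v):
        if v not in ("crossover4x4", "parallel_mad"):
            raise ValueError(f"unknown design {v!r}")
        return v

    @field_validator("sampling_times_h")
    @classmethod
    def _increasing(cls, v):
        if np.any(np.diff(v) <= 0) or v[0] <= 0:
            raise ValueError("sampling_times_h must be positive, strictly increasing")
        return v

    @model_validator(mode="after")
    def _check(self):
        if self.design == "crossover4x4":
            seqs = self.sequences
            labels = sorted(seqs[0])
            for s in seqs:
                if sorted(s) != labels:
                    raise ValueError("each sequence must use every treatment once")
            for p in range(len(seqs[0])):
                if sorted(s[p] for s in seqs) != labels:
                    raise ValueError("each treatment must appear once per period")
            if self.n_subjects % len(seqs):
                raise ValueError("n_subjects must be a multiple of the sequence count")
        return self


@dataclass
class SimulatedStudy:
    """A simulated dataset plus the realized ground truth."""

    ecg: pd.DataFrame
    pk: pd.DataFrame
    truth: pd.DataFrame       # per-subject realized parameters
    truth_params: dict        # population-level generating values
    config: StudyConfig


def two_compartment_oral(t, dose_mg, ka, cl_f, v1, v2=0.0, q=0.0):
    """Plasma concentration (ng/mL) after a single oral dose at t = 0.

    Closed-form solution of the two-compartment model with first-order
    absorption; ``q = 0`` uses the one-compartment form, and coincident rate
    constants are handled by the exponential limiting form (``ka -> k10``) or
    an infinitesimal rate split. Dose in mg, volumes in L, clearances in L/h.
    """
    t = np.asarray(t, dtype=float)
    dose_ug = dose_mg * 1000.0  # ng/mL == ug/L
    k10 = cl_f / v1
    tt = np.maximum(t, 0.0)

    if q == 0.0:
        if abs(ka - k10) < 1e-9 * ka:
            conc = dose_ug / v1 * k10 * tt * np.exp(-k10 * tt)
        else:
            conc = (dose_ug * ka / (v1 * (ka - k10))
                    * (np.exp(-k10 * tt) - np.exp(-ka * tt)))
        return np.where(t > 0, conc, 0.0)

    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    # infinitesimal split keeps the three exponentials distinct
    for r in (alpha, beta):
        if abs(ka - r) < 1e-9 * ka:
            ka = ka * (1.0 + 1e-8)
    if abs(alpha - beta) < 1e-12 * alpha:
        alpha = alpha * (1.0 + 1e-8)

    f = dose_ug * ka / v1
    A = f * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    B = f * (k21 - beta) / ((ka - beta) * (alpha - beta))
    C = f * (k21 - ka) / ((alpha - ka) * (beta - ka))
    conc = (A * np.exp(-alpha * tt) + B * np.exp(-beta * tt)
            + C * np.exp(-ka * tt))
    return np.where(t > 0, np.maximum(conc, 0.0), 0.0)


def simulate_pk_profile(pk: PkParams, dose_mg: float, times_h) -> np.ndarray:
    """Single-dose concentration profile for one parameter set."""
    return two_compartment_oral(times_h, dose_mg, pk.ka, pk.cl_f, pk.v1, pk.v2, pk.q)


def _multidose_profile(pk: PkParams, dose_mg, times_h, tau_h=24.0, n_doses=1):
    """Once-every-``tau_h`` superposition of ``n_doses`` identical doses."""
    t = np.asarray(times_h, dtype=float)
    conc = np.zeros_like(t)
    for d in range(n_doses):
        conc = conc + simulate_pk_profile(pk, dose_mg, t - d * tau_h)
    return conc


def accumulation_ratio(t_half_h: float, tau_h: float = 24.0) -> float:
    """Steady-state accumulation ratio 1 / (1 - 2^(-tau/t_half))."""
    if t_half_h <= 0 or tau_h <= 0:
        raise ValueError("t_half_h and tau_h must be positive")
    return float(1.0 / (1.0 - 2.0 ** (-tau_h / t_half_h)))


def dose_label(dose_mg: float) -> str:
    return f"active_{dose_mg:g}mg"


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigendecomposition fallback)."""
    mat = np.asarray(mat, dtype=float)
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _lognormal_iiv(rng, typical: float, cv_percent: float) -> float:
    if cv_percent <= 0:
        return typical
    sd = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    return float(typical * np.exp(rng.normal(0.0, sd)))


def _subject_pk(rng, pk: PkParams) -> PkParams:
    values = pk.model_dump()
    for name, cv in pk.iiv_cv_percent.items():
        values[name] = _lognormal_iiv(rng, values[name], cv)
    return PkParams(**values)


class _SubjectQtc:
    """Realized subject-level QTc parameters."""

    def __init__(self, rng, qtc: QtcParams):
        self.baseline = float(rng.normal(qtc.baseline_mean_ms, qtc.baseline_sd_ms))
        chol = _chol_psd(np.asarray(qtc.omega, dtype=float))
        self.eta = chol @ rng.standard_normal(2)       # drug-arm intercept/slope
        self.eta_moxi = chol @ rng.standard_normal(2)  # positive-control arm

    def etas(self, treatment):
        return self.eta_moxi if treatment == MOXIFLOXACIN else self.eta


def _diurnal(qtc: QtcParams, time_post_dose_h):
    clock = qtc.dosing_clock_h + np.asarray(time_post_dose_h, dtype=float)
    a1, a2 = qtc.diurnal_amplitudes_ms
    p1, p2 = qtc.diurnal_phases_h
    return (a1 * np.cos(2 * np.pi * (clock - p1) / 24.0)
            + a2 * np.cos(2 * np.pi * (clock - p2) / 12.0))


def _day_of(time_h: float) -> int:
    """Nominal day of a single-dose timepoint (dose on day 1)."""
    return 1 + int(max(time_h, 0.0) // 24) if time_h > 0 else 1


def _emit_ecg(records, rng, cfg, subj_qtc, *, subject_id, treatment, period,
              day, time_h, conc, active_post, slope, theta0, cohort=None):
    """Generate one ECG record: QTcF by the generative model, QT from the
    inverse Fridericia transform of a simulated RR."""
    qtc = cfg.qtc
    eta0, eta1 = subj_qtc.etas(treatment)
    qtcf = (subj_qtc.baseline + float(_diurnal(qtc, time_h))
            + rng.normal(0.0, qtc.residual_sd_ms))
    hr_shift = 0.0
    if active_post:
        qtcf += theta0 + eta0 + (slope + eta1) * conc
        if cfg.hr_effect_bpm and (cfg.hr_effect_days is None
                                  or day in cfg.hr_effect_days):
            hr_shift = cfg.hr_effect_bpm
    rr_centre = 60000.0 / (60000.0 / qtc.rr_mean_ms + hr_shift)
    rr = max(rr_centre + rng.normal(0.0, qtc.rr_sd_ms), 300.0)
    qt = qtcf * np.cbrt(rr / 1000.0)
    rec = {
        "subject_id": subject_id, "treatment": treatment, "period": period,
        "day": day, "time_h": time_h, "qt_ms": qt, "rr_ms": rr,
    }
    if cohort is not None:
        rec["cohort"] = cohort
    records.append(rec)


def _simulate_crossover(cfg: StudyConfig) -> SimulatedStudy:
    qtc = cfg.qtc
    arm_of = {"C": PLACEBO, "D": MOXIFLOXACIN}
    for label, dose in zip("AB", cfg.doses_mg):
        arm_of[label] = dose_label(dose)
    dose_of = {dose_label(d): d for d in cfg.doses_mg}

    ecg_rows: list = []
    pk_rows: list = []
    truth_rows: list = []
    n_seq = len(cfg.sequences)
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:03d}"
        rng = np.random.default_rng([cfg.seed, s])
        sequence = cfg.sequences[s % n_seq]
        subj_pk = _subject_pk(rng, cfg.pk)
        subj_moxi_pk = (_subject_pk(rng, cfg.moxifloxacin.pk)
                        if cfg.moxifloxacin else None)
        subj_qtc = _SubjectQtc(rng, qtc)
        truth_rows.append({
            "subject_id": sid, "sequence": "/".join(sequence),
            "baseline_ms": subj_qtc.baseline,
            "eta0_ms": subj_qtc.eta[0], "eta1_ms_per_ng_ml": subj_qtc.eta[1],
            "cl_f": subj_pk.cl_f, "v1": subj_pk.v1,
        })

        for period, label in enumerate(sequence, start=1):
            treatment = arm_of[label]
            if treatment == PLACEBO:
                conc_fn, slope, theta0 = None, 0.0, 0.0
            elif treatment == MOXIFLOXACIN:
                moxi = cfg.moxifloxacin
                conc_fn = lambda t: simulate_pk_profile(subj_moxi_pk, moxi.dose_mg, t)
                slope, theta0 = moxi.slope_ms_per_ng_ml, moxi.theta0_ms
            else:
                dose = dose_of[treatment]
                conc_fn = lambda t, d=dose: simulate_pk_profile(subj_pk, d, t)
                slope, theta0 = qtc.slope_ms_per_ng_ml, qtc.theta0_ms

            for t in cfg.predose_times_h:
                _emit_ecg(ecg_rows, rng, cfg, subj_qtc, subject_id=sid,
                          treatment=treatment, period=period, day=1, time_h=t,
                          conc=0.0, active_post=False, slope=slope, theta0=theta0)

            times = np.asarray(cfg.sampling_times_h)
            concs = conc_fn(times) if conc_fn is not None else np.zeros_like(times)
            for t, c in zip(times, concs):
                _emit_ecg(ecg_rows, rng, cfg, subj_qtc, subject_id=sid,
                          treatment=treatment, period=period, day=_day_of(t),
                          time_h=float(t), conc=float(c),
                          active_post=(treatment != PLACEBO),
                          slope=slope, theta0=theta0)
            if treatment != PLACEBO:
                analyte = (ANALYTE_MOXIFLOXACIN if treatment == MOXIFLOXACIN
                           else ANALYTE_DRUG)
                for t, c in zip(times, concs):
                    pk_rows.append({
                        "subject_id": sid, "treatment": treatment,
                        "period": period, "day": _day_of(float(t)),
                        "time_h": float(t), "analyte": analyte,
                        "conc": float(c), "lloq_flag": False,
                    })

    truth_params = {
        "theta0_ms": qtc.theta0_ms,
        "theta1_ms_per_ng_ml": qtc.slope_ms_per_ng_ml,
        "moxi_theta0_ms": cfg.moxifloxacin.theta0_ms if cfg.moxifloxacin else None,
        "moxi_slope_ms_per_ng_ml": (cfg.moxifloxacin.slope_ms_per_ng_ml
                                    if cfg.moxifloxacin else None),
    }
    return SimulatedStudy(
        ecg=pd.DataFrame(ecg_rows), pk=pd.DataFrame(pk_rows),
        truth=pd.DataFrame(truth_rows), truth_params=truth_params, config=cfg,
    )


def _simulate_parallel_mad(cfg: StudyConfig) -> SimulatedStudy:
    qtc = cfg.qtc
    n_days = max(cfg.n_days, max(cfg.ecg_days))
    ecg_rows: list = []
    pk_rows: list = []
    truth_rows: list = []

    roster = []  # (cohort index, treatment, dose)
    for ci, cohort in enumerate(cfg.cohorts, start=1):
        roster += [(ci, dose_label(cohort.dose_mg), cohort.dose_mg)] * cohort.n_active
        roster += [(ci, PLACEBO, 0.0)] * cohort.n_placebo

    for s, (ci, treatment, dose) in enumerate(roster):
        sid = f"S{s + 1:03d}"
        rng = np.random.default_rng([cfg.seed, s])
        subj_pk = _subject_pk(rng, cfg.pk)
        subj_qtc = _SubjectQtc(rng, qtc)
        truth_rows.append({
            "subject_id": sid, "cohort": ci, "treatment": treatment,
            "dose_mg": dose, "baseline_ms": subj_qtc.baseline,
            "eta0_ms": subj_qtc.eta[0], "eta1_ms_per_ng_ml": subj_qtc.eta[1],
            "cl_f": subj_pk.cl_f, "v1": subj_pk.v1,
        })
        active = treatment != PLACEBO
        for day in cfg.ecg_days:
            offset = 24.0 * (day - 1)
            # pre-dose samples on later days carry the accumulated trough
            pre = np.asarray(cfg.predose_times_h)
            pre_concs = (_multidose_profile(subj_pk, dose, offset + pre,
                                            tau_h=24.0, n_doses=n_days)
                         if active else np.zeros_like(pre))
            for t, c in zip(pre, pre_concs):
                _emit_ecg(ecg_rows, rng, cfg, subj_qtc, subject_id=sid,
                          treatment=treatment, period=1, day=day,
                          time_h=float(t), conc=float(c),
                          active_post=(active and day > 1),
                          slope=qtc.slope_ms_per_ng_ml, theta0=qtc.theta0_ms,
                          cohort=ci)
            times = np.asarray(cfg.sampling_times_h)
            if active:
                concs = _multidose_profile(subj_pk, dose, offset + times,
                                           tau_h=24.0, n_doses=n_days)
            else:
                concs = np.zeros_like(times)
            for t, c in zip(times, concs):
                _emit_ecg(ecg_rows, rng, cfg, subj_qtc, subject_id=sid,
                          treatment=treatment, period=1, day=day,
                          time_h=float(t), conc=float(c), active_post=active,
                          slope=qtc.slope_ms_per_ng_ml, theta0=qtc.theta0_ms,
                          cohort=ci)
            if active:
                for t, c in zip(times, concs):
                    pk_rows.append({
                        "subject_id": sid, "treatment": treatment, "period": 1,
                        "day": day, "time_h": float(t),
                        "analyte": ANALYTE_DRUG, "conc": float(c),
                        "lloq_flag": False, "cohort": ci,
                    })

    truth_params = {
        "theta0_ms": qtc.theta0_ms,
        "theta1_ms_per_ng_ml": qtc.slope_ms_per_ng_ml,
        "moxi_theta0_ms": None,
        "moxi_slope_ms_per_ng_ml": None,
    }
    return SimulatedStudy(
        ecg=pd.DataFrame(ecg_rows), pk=pd.DataFrame(pk_rows),
        truth=pd.DataFrame(truth_rows), truth_params=truth_params, config=cfg,
    )


def simulate_study(config: StudyConfig) -> SimulatedStudy:
    """Simulate a full long-format ECG + PK dataset; deterministic given seed."""
    if config.design == "crossover4x4":
        return _simulate_crossover(config)
    return _simulate_parallel_mad(config)


def tqt_reference(seed: int = 0, **overrides) -> StudyConfig:
    """Reference crossover thorough-QT configuration (n = 28, slope 0.0054)."""
    return StudyConfig(seed=seed, **overrides)


def mad_reference(seed: int = 0, **overrides) -> StudyConfig:
    """Reference parallel MAD configuration.

    Five 3:1 cohorts dosed once daily for 10 days, ECG/PK on days 1 and 10,
    shorter within-day sampling, and a negative concentration effect of
    -0.15 ms per ng/mL at the low (tens of ng/mL) MAD concentration scale.
    """
    qtc = QtcParams(slope_ms_per_ng_ml=-0.15)
    defaults = dict(
        design="parallel_mad",
        n_subjects=sum(c.n_active + c.n_placebo for c in DEFAULT_MAD_COHORTS),
        sampling_times_h=(0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0),
        qtc=qtc,
        moxifloxacin=None,
        n_days=10,
        ecg_days=(1, 10),
        seed=seed,
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)
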