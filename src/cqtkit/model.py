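"""The pre-specified linear mixed-effect concentration-QTc model.

The primary analysis regresses the placebo-corrected, baseline-adjusted QTcF
change (ddQTcF, ms) on the time-matched plasma concentration C (ng/mL)::

    ddQTcF_ij = (theta0 + eta0_i) + (theta1 + eta1_i) C_ij
                + theta2 (B_i - B_bar) + eps_ij

with subject-level random intercept/slope ``(eta0, eta1) ~ N(0, Omega)``
(unstructured), residual ``eps ~ N(0, sigma2)``, and ``B_i`` the subject's
baseline QTcF centred at ``B_bar``. Estimation is REML (:mod:`cqtkit.mixedlm`).

Regulatory reading of the fit: a QTc-prolonging effect is excluded when the
upper bound of the two-sided 90% CI of the predicted mean ddQTcF at the
concentration of interest is strictly below 10 ms; assay sensitivity of the
study is demonstrated when, for the positive-control arm (moxifloxacin), the
lower bound at its observed geometric mean Cmax is strictly above 5 ms.

``ConcentrationQtcModel`` is a scikit-learn style estimator; the module-level
functions (:func:`fit_cqtc`, :func:`predict_ddqtcf`, the verdicts) are thin
wrappers around it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .mixedlm import DEFAULT_STARTS, EstimationError, REMLProblem

__all__ = [
    "CqtcFit",
    "Prediction",
    "Verdict",
    "ConcentrationQtcModel",
    "fit_cqtc",
    "predict_ddqtcf",
    "concentration_of_interest",
    "assess_no_prolongation",
    "assess_assay_sensitivity",
    "verdict_from_prediction",
    "power_paired_exclusion",
]


@dataclass
class CqtcFit:
    """A fitted (or externally specified) concentration-QTc model.

    ``theta0`` is the intercept (ms), ``theta1`` the concentration slope
    (ms per ng/mL), ``theta2`` the coefficient of the centred baseline QTcF
    (ms per ms; ``None`` when the covariate is excluded). ``fixed_cov`` is the
    covariance of the fixed effects, ``omega`` the 2x2 random intercept/slope
    covariance, and ``sigma2`` the residual variance (ms^2).
    """

    theta0: float
    theta1: float
    theta2: float | None = None
    fixed_cov: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    sigma2: float = float("nan")
    baseline_centre: float = 0.0
    n_subjects: int = 0
    n_obs: int = 0
    reml_criterion: float = float("nan")
    converged: bool = True

    @property
    def n_fixed(self) -> int:
        return 2 if self.theta2 is None else 3

    @property
    def df(self) -> int:
        """CI degrees of freedom: subjects minus fixed effects (floor 1)."""
        return max(self.n_subjects - self.n_fixed, 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_cov"] = np.asarray(self.fixed_cov).tolist()
        d["omega"] = np.asarray(self.omega).tolist()
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass
class Prediction:
    """Model-predicted mean ddQTcF at a concentration, with a two-sided CI."""

    conc: float
    mean_ms: float
    ci_lower_ms: float
    ci_upper_ms: float
    level: float = 0.90


@dataclass
class Verdict:
    """A regulatory pass/fail read-out of one CI bound against a threshold."""

    kind: str  # "no_prolongation" | "assay_sensitivity"
    conc: float
    bound_ms: float
    threshold_ms: float
    passed: bool


class ConcentrationQtcModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the linear mixed-effect C-QTc model.

    Parameters
    ----------
    include_baseline : bool
        Include the centred subject baseline QTcF as a fixed covariate
        (requires a second column in X).
    random_slope : bool
        Include the subject-level random slope (random intercept always on).
    baseline_centre : float or None
        Centring constant for the baseline covariate; ``None`` (default) uses
        the mean of the subject-level baselines over subjects contributing
        rows. Fixed effects are invariant to this choice up to the implied
        intercept shift.
    level : float
        Default two-sided confidence level for predictions.

    Call ``fit(X, y, groups=subject_ids)`` with ``X`` of shape (n, 1)
    (concentration) or (n, 2) (concentration, baseline QTcF) and ``y`` the
    ddQTcF responses in ms.
    """

    def __init__(self, include_baseline: bool = True, random_slope: bool = True,
                 baseline_centre: float | None = None, level: float = 0.90,
                 starts=DEFAULT_STARTS):
        self.include_baseline = include_baseline
        self.random_slope = random_slope
        self.baseline_centre = baseline_centre
        self.level = level
        self.starts = starts

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if groups is None:
            raise ValueError("groups (subject identifiers) are required")
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise EstimationError("at least 2 subjects are required")
        conc = X[:, 0]
        if len(np.unique(conc)) < 2:
            raise EstimationError(
                "singular design: at least 2 distinct concentrations required"
            )
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(y)):
            raise ValueError("concentrations and responses must be finite")

        design = [np.ones_like(conc), conc]
        centre = 0.0
        if self.include_baseline:
            if X.shape[1] < 2:
                raise ValueError("include_baseline=True requires a baseline column")
            baseline = X[:, 1]
            if self.baseline_centre is None:
                # mean of subject-level baselines over contributing subjects
                per_subject = pd.Series(baseline).groupby(pd.Series(groups)).mean()
                centre = float(per_subject.mean())
            else:
                centre = float(self.baseline_centre)
            design.append(baseline - centre)
        Xd = np.column_stack(design)
        Z = np.column_stack([np.ones_like(conc), conc]) if self.random_slope \
            else np.ones((len(conc), 1))

        res = REMLProblem(y, Xd, Z, groups).fit(starts=self.starts)

        omega = res.omega
        if omega.shape != (2, 2):  # random intercept only: embed in 2x2
            full = np.zeros((2, 2))
            full[: omega.shape[0], : omega.shape[1]] = omega
            omega = full
        self.fit_ = CqtcFit(
            theta0=float(res.beta[0]),
            theta1=float(res.beta[1]),
            theta2=float(res.beta[2]) if self.include_baseline else None,
            fixed_cov=res.beta_cov,
            omega=omega,
            sigma2=float(res.sigma2),
            baseline_centre=centre,
            n_subjects=int(res.n_groups),
            n_obs=int(res.n_obs),
            reml_criterion=float(res.loglik),
            converged=res.converged,
        )
        self.theta0_ = self.fit_.theta0
        self.theta1_ = self.fit_.theta1
        self.theta2_ = self.fit_.theta2
        self.fixed_cov_ = self.fit_.fixed_cov
        self.omega_ = self.fit_.omega
        self.sigma2_ = self.fit_.sigma2
        self.baseline_centre_ = centre
        self.n_subjects_ = self.fit_.n_subjects
        self.n_obs_ = self.fit_.n_obs
        self.reml_criterion_ = self.fit_.reml_criterion
        return self

    def predict(self, X):
        """Mean ddQTcF at the rows of X (concentration [, baseline])."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self.theta0_ + self.theta1_ * X[:, 0]
        if self.theta2_ is not None:
            if X.shape[1] < 2:
                raise ValueError("model was fitted with a baseline covariate")
            out = out + self.theta2_ * (X[:, 1] - self.baseline_centre_)
        return out

    def predict_interval(self, conc, level: float | None = None) -> Prediction:
        """Mean ddQTcF and two-sided CI at one concentration (centred baseline)."""
        return predict_ddqtcf(self.fit_, conc, self.level if level is None else level)


def fit_cqtc(rows: pd.DataFrame, level: float = 0.90, *,
             include_baseline: bool = True, random_slope: bool = True,
             baseline_centre: float | None = None) -> CqtcFit:
    """Fit the C-QTc model to a model-ready observation table.

    ``rows`` must carry columns ``conc``, ``ddqtcf_ms``, ``subject_id`` and
    (when ``include_baseline``) ``baseline_qtcf_ms``.
    """
    cols = ["conc"] + (["baseline_qtcf_ms"] if include_baseline else [])
    model = ConcentrationQtcModel(
        include_baseline=include_baseline,
        random_slope=random_slope,
        baseline_centre=baseline_centre,
        level=level,
    )
    model.fit(rows[cols].to_numpy(), rows["ddqtcf_ms"].to_numpy(),
              groups=rows["subject_id"].to_numpy())
    return model.fit_


def predict_ddqtcf(fit: CqtcFit, conc: float, level: float = 0.90) -> Prediction:
    """Predicted mean ddQTcF at ``conc`` (ng/mL), at centred baseline 0.

    The CI uses the t distribution with ``fit.df`` degrees of freedom and the
    quadratic variance form ``v00 + conc^2 v11 + 2 conc v01`` from the
    fixed-effect covariance.
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    V = np.asarray(fit.fixed_cov, dtype=float)
    mean = fit.theta0 + fit.theta1 * conc
    var = float(V[0, 0] + conc**2 * V[1, 1] + 2.0 * conc * V[0, 1])
    se = np.sqrt(max(var, 0.0))
    tq = stats.t.ppf(0.5 + level / 2.0, fit.df)
    return Prediction(
        conc=float(conc),
        mean_ms=float(mean),
        ci_lower_ms=float(mean - tq * se),
        ci_upper_ms=float(mean + tq * se),
        level=level,
    )


def concentration_of_interest(gmean_cmax_ss: float, factor: float = 2.0,
                              round_to_integer: bool = True) -> float:
    """Concentration of interest: steady-state gmean Cmax times a safety factor.

    The factor (default 2) covers potential intrinsic and extrinsic effects
    such as drug-drug interactions; the result is reported to the nearest
    integer ng/mL by convention.
    """
    if gmean_cmax_ss <= 0 or factor <= 0:
        raise ValueError("gmean_cmax_ss and factor must be positive")
    out = gmean_cmax_ss * factor
    return float(round(out)) if round_to_integer else float(out)


def verdict_from_prediction(pred: Prediction, kind: str, threshold_ms: float) -> Verdict:
    """Read a verdict off an existing prediction's CI bound (strict inequality)."""
    if kind == "no_prolongation":
        bound = pred.ci_upper_ms
        passed = bound < threshold_ms
    elif kind == "assay_sensitivity":
        bound = pred.ci_lower_ms
        passed = bound > threshold_ms
    else:
        raise ValueError(f"unknown verdict kind {kind!r}")
    return Verdict(kind=kind, conc=pred.conc, bound_ms=float(bound),
                   threshold_ms=float(threshold_ms), passed=bool(passed))


def assess_no_prolongation(fit: CqtcFit, conc: float, threshold_ms: float = 10.0,
                           level: float = 0.90) -> Verdict:
    """Exclusion of a QTc-prolonging effect: CI upper bound strictly < threshold."""
    pred = predict_ddqtcf(fit, conc, level)
    return verdict_from_prediction(pred, "no_prolongation", threshold_ms)


def assess_assay_sensitivity(fit_moxi: CqtcFit, gmean_cmax: float,
                             threshold_ms: float = 5.0,
                             level: float = 0.90) -> Verdict:
    """Assay sensitivity: positive-control CI lower bound strictly > threshold."""
    pred = predict_ddqtcf(fit_moxi, gmean_cmax, level)
    return verdict_from_prediction(pred, "assay_sensitivity", threshold_ms)


def power_paired_exclusion(n: int, sd_ddqtcf: float, margin_ms: float = 10.0,
                           true_effect_ms: float = 0.0,
                           alpha: float = 0.05) -> float:
    """Power of a paired t-test to exclude a QTc effect of ``margin_ms``.

    The exclusion succeeds when the one-sided upper ``1 - alpha`` bound of the
    mean ddQTcF falls below the margin; under a true effect ``delta`` the test
    statistic is noncentral t with ``n - 1`` degrees of freedom and
    noncentrality ``(delta - margin) / (sd / sqrt(n))``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if sd_ddqtcf <= 0:
        raise ValueError("sd_ddqtcf must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha, df)
    ncp = (true_effect_ms - margin_ms) / (sd_ddqtcf / np.sqrt(n))
    return float(stats.nct.cdf(-t_crit, df, ncp))
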