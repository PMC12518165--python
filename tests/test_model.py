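import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from cqtkit.model import (
    ConcentrationQtcModel,
    CqtcFit,
    Prediction,
    assess_assay_sensitivity,
    assess_no_prolongation,
    concentration_of_interest,
    fit_cqtc,
    power_paired_exclusion,
    predict_ddqtcf,
    verdict_from_prediction,
)


@pytest.mark.parametrize(
    "theta0,theta1,conc,expected_1dp",
    [(-2.7863, 0.0054, 86.0, -2.3),
     (-2.7863, 0.0054, 180.7, -1.8),
     (2.5997, 0.0044, 2367.1, 13.0)],
)
def test_point_prediction_from_coefficients(theta0, theta1, conc, expected_1dp):
    """A model built from externally estimated coefficients predicts the mean
    ddQTcF theta0 + theta1*conc at centred baseline 0."""
    fit = CqtcFit(theta0=theta0, theta1=theta1)
    pred = predict_ddqtcf(fit, conc)
    assert round(pred.mean_ms, 1) == expected_1dp


def test_prediction_at_zero_concentration_is_intercept():
    fit = CqtcFit(theta0=-2.7863, theta1=0.0054)
    assert predict_ddqtcf(fit, 0.0).mean_ms == pytest.approx(-2.7863)


def test_prediction_rejects_negative_concentration():
    with pytest.raises(ValueError):
        predict_ddqtcf(CqtcFit(theta0=0.0, theta1=1.0), -1.0)


@pytest.mark.parametrize(
    "value,factor,expected",
    [(43.1, 2.0, 86.0), (50.0, 2.0, 100.0), (86.2, 1.0, 86.0)],
)
def test_concentration_of_interest(value, factor, expected):
    assert concentration_of_interest(value, factor) == expected


def test_concentration_of_interest_rejects_nonpositive():
    with pytest.raises(ValueError):
        concentration_of_interest(-1.0)


@pytest.mark.parametrize(
    "upper,passed",
    [(-0.9, True), (9.99, True), (10.0, False), (12.0, False)],
)
def test_no_prolongation_verdict_is_strict(upper, passed):
    pred = Prediction(conc=86.0, mean_ms=upper - 1.0, ci_lower_ms=upper - 2.0,
                      ci_upper_ms=upper)
    v = verdict_from_prediction(pred, "no_prolongation", 10.0)
    assert v.passed is passed
    assert v.bound_ms == upper


@pytest.mark.parametrize(
    "lower,passed",
    [(8.8, True), (5.0, False), (4.0, False)],
)
def test_assay_sensitivity_verdict_is_strict(lower, passed):
    pred = Prediction(conc=2367.1, mean_ms=lower + 4.0, ci_lower_ms=lower,
                      ci_upper_ms=lower + 8.0)
    v = verdict_from_prediction(pred, "assay_sensitivity", 5.0)
    assert v.passed is passed


def test_verdicts_from_a_fitted_model_use_the_ci_bounds():
    # deterministic covariance: se(86 ng/mL) known in closed form
    cov = np.diag([0.5, 1e-6, 0.0])
    fit = CqtcFit(theta0=-2.7863, theta1=0.0054, theta2=-0.3455,
                  fixed_cov=cov, n_subjects=27, n_obs=500)
    pred = predict_ddqtcf(fit, 86.0, level=0.90)
    se = np.sqrt(0.5 + 86.0**2 * 1e-6)
    tq = stats.t.ppf(0.95, 27 - 3)
    assert pred.ci_upper_ms == pytest.approx(pred.mean_ms + tq * se)
    assert assess_no_prolongation(fit, 86.0).passed
    moxi = CqtcFit(theta0=2.5997, theta1=0.0044, fixed_cov=np.diag([1.0, 1e-7]),
                   n_subjects=27)
    assert assess_assay_sensitivity(moxi, 2367.1).passed


def test_ci_halfwidth_grows_beyond_variance_minimizing_concentration():
    cov = np.array([[1.0, -0.01, 0.0], [-0.01, 0.001, 0.0], [0.0, 0.0, 0.0]])
    fit = CqtcFit(theta0=0.0, theta1=0.01, theta2=0.0, fixed_cov=cov,
                  n_subjects=20)
    c_star = -cov[0, 1] / cov[1, 1]  # minimizer of the quadratic variance form
    concs = np.linspace(c_star, c_star + 200, 30)
    widths = [predict_ddqtcf(fit, c).ci_upper_ms - predict_ddqtcf(fit, c).ci_lower_ms
              for c in concs]
    assert np.all(np.diff(widths) >= -1e-12)


def test_fixed_effects_invariant_to_baseline_centre(mixed_effects_data):
    """Changing the centring constant shifts theta0 by theta2*delta and leaves
    theta1, theta2 unchanged."""
    f1 = fit_cqtc(mixed_effects_data, baseline_centre=400.0)
    f2 = fit_cqtc(mixed_effects_data, baseline_centre=410.0)
    assert f1.theta1 == pytest.approx(f2.theta1, rel=1e-5)
    assert f1.theta2 == pytest.approx(f2.theta2, rel=1e-5)
    assert f1.theta0 == pytest.approx(f2.theta0 + f2.theta2 * (-10.0), abs=1e-4)


def test_estimator_follows_sklearn_conventions(mixed_effects_data):
    df = mixed_effects_data
    est = ConcentrationQtcModel(include_baseline=False)
    params = est.get_params()
    assert params["include_baseline"] is False
    cloned = clone(est)
    X = df[["conc"]].to_numpy()
    cloned.fit(X, df["ddqtcf_ms"], groups=df["subject_id"])
    assert hasattr(cloned, "theta1_")
    preds = cloned.predict(np.array([[0.0], [100.0]]))
    assert preds[1] - preds[0] == pytest.approx(100.0 * cloned.theta1_)


def test_estimator_requires_groups_and_multiple_subjects(mixed_effects_data):
    df = mixed_effects_data
    est = ConcentrationQtcModel(include_baseline=False)
    with pytest.raises(ValueError):
        est.fit(df[["conc"]].to_numpy(), df["ddqtcf_ms"])
    one = df[df["subject_id"] == "S00"]
    with pytest.raises(Exception, match="subjects"):
        est.fit(one[["conc"]].to_numpy(), one["ddqtcf_ms"],
                groups=one["subject_id"])


def test_power_limits_and_boundaries():
    # vanishing variability: certain exclusion
    assert power_paired_exclusion(24, 1e-6, 10.0, 0.0, 0.05) == pytest.approx(1.0)
    # true effect at the margin: power equals alpha
    assert power_paired_exclusion(24, 8.0, 10.0, 10.0, 0.05) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        power_paired_exclusion(1, 8.0)
    with pytest.raises(ValueError):
        power_paired_exclusion(24, 0.0)


def test_power_matches_monte_carlo_oracle():
    """Noncentral-t power against a 10^5-replicate simulation of the paired
    exclusion test (n = 24, sd 8, no true effect)."""
    n, sd, margin, alpha = 24, 8.0, 10.0, 0.05
    analytic = power_paired_exclusion(n, sd, margin, 0.0, alpha)
    rng = np.random.default_rng(99)
    reps = 100_000
    samples = rng.normal(0.0, sd, size=(reps, n))
    mean = samples.mean(axis=1)
    s = samples.std(axis=1, ddof=1)
    upper = mean + stats.t.ppf(1 - alpha, n - 1) * s / np.sqrt(n)
    mc = float((upper < margin).mean())
    assert analytic == pytest.approx(mc, abs=0.005)
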