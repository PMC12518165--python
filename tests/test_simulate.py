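import numpy as np
import pandas as pd
import pytest

from cqtkit.model import fit_cqtc
from cqtkit.nca import geometric_summary
from cqtkit.pipeline import derive_model_rows
from cqtkit.simulate import (
    PkParams,
    QtcParams,
    StudyConfig,
    accumulation_ratio,
    mad_reference,
    simulate_pk_profile,
    simulate_study,
    tqt_reference,
    two_compartment_oral,
)


def test_same_seed_gives_bit_identical_datasets():
    a = simulate_study(tqt_reference(seed=5, n_subjects=4))
    b = simulate_study(tqt_reference(seed=5, n_subjects=4))
    pd.testing.assert_frame_equal(a.ecg, b.ecg)
    pd.testing.assert_frame_equal(a.pk, b.pk)
    c = simulate_study(tqt_reference(seed=6, n_subjects=4))
    assert not a.ecg["qt_ms"].equals(c.ecg["qt_ms"])


def test_concentration_is_zero_at_and_before_dosing():
    t = np.array([-1.0, 0.0, 0.5, 2.0])
    conc = two_compartment_oral(t, 32.0, ka=1.2, cl_f=3.0, v1=58.0, v2=45.0, q=6.0)
    assert conc[0] == 0.0 and conc[1] == 0.0
    assert np.all(conc[2:] > 0)


def test_q_zero_reduces_to_one_compartment_closed_form():
    """The q = 0 structural limit equals the one-compartment solution, and a
    vanishing inter-compartmental clearance approaches it."""
    t = np.linspace(0.1, 48, 200)
    ka, cl, v1, dose = 1.0, 3.0, 50.0, 16.0
    k = cl / v1
    expected = (dose * 1000.0 * ka / (v1 * (ka - k))
                * (np.exp(-k * t) - np.exp(-ka * t)))
    got = two_compartment_oral(t, dose, ka, cl, v1, v2=45.0, q=0.0)
    np.testing.assert_allclose(got, expected, rtol=1e-12)
    near = two_compartment_oral(t, dose, ka, cl, v1, v2=45.0, q=1e-7)
    np.testing.assert_allclose(near, expected, rtol=1e-4)


def test_coincident_absorption_elimination_limit():
    t = np.linspace(0.1, 24, 100)
    k = 0.2
    got = two_compartment_oral(t, 10.0, ka=k, cl_f=k * 40.0, v1=40.0, v2=0.0, q=0.0)
    expected = 10000.0 / 40.0 * k * t * np.exp(-k * t)
    np.testing.assert_allclose(got, expected, rtol=1e-6)


def test_reference_exposure_matches_intended_ranges():
    """At the reference crossover configuration, the geometric mean Cmax of
    the high dose lands in the intended 260-617 ng/mL window and every
    subject's tmax falls within 0.5-4 h."""
    sim = simulate_study(tqt_reference(seed=11))
    pk32 = sim.pk[sim.pk["treatment"] == "active_32mg"]
    cmax = pk32.groupby("subject_id")["conc"].max()
    g = geometric_summary(cmax)["gmean"]
    assert 260.0 <= g <= 617.0
    tmax = pk32.loc[pk32.groupby("subject_id")["conc"].idxmax(), "time_h"]
    assert (tmax.between(0.5, 4.0)).mean() >= 0.95


def test_crossover_allocation_is_balanced():
    sim = simulate_study(tqt_reference(seed=1))
    counts = sim.truth["sequence"].value_counts()
    assert len(counts) == 4 and (counts == 7).all()


def test_sequences_must_form_a_latin_square():
    with pytest.raises(ValueError):
        StudyConfig(sequences=(("A", "B", "C", "D"),) * 4, n_subjects=4)


def test_accumulation_ratio_matches_half_life():
    assert accumulation_ratio(29.0, 24.0) == pytest.approx(2.29, abs=0.01)
    with pytest.raises(ValueError):
        accumulation_ratio(-1.0)


def test_mad_day10_trough_shows_accumulation():
    """Once-daily dosing for 10 days accumulates roughly per the terminal
    half-life (ratio ~2-3 at t_half ~26 h)."""
    sim = simulate_study(mad_reference(seed=4))
    pk = sim.pk
    highest = pk[pk["treatment"] == "active_5mg"]
    by_day = highest.groupby(["day", "time_h"])["conc"].mean().unstack(0)
    ratio = (by_day[10] / by_day[1]).mean()
    assert 1.8 <= ratio <= 3.2


def _noise_free(slope, **overrides):
    from cqtkit.simulate import MoxiParams

    qtc = QtcParams(
        slope_ms_per_ng_ml=slope,
        omega=((0.0, 0.0), (0.0, 0.0)),
        residual_sd_ms=0.0,
        baseline_sd_ms=5.0,
        theta0_ms=0.0,
    )
    moxi = MoxiParams(slope_ms_per_ng_ml=0.0, theta0_ms=0.0)
    return tqt_reference(qtc=qtc, moxifloxacin=moxi, n_subjects=8, **overrides)


def test_zero_noise_zero_slope_yields_identically_zero_ddqtcf():
    """Null chain: no noise, no effect -> the derived ddQTcF is exactly 0
    (diurnal rhythm cancelled by time-matched placebo correction)."""
    sim = simulate_study(_noise_free(0.0, seed=21))
    rows, _ = derive_model_rows(sim.ecg, sim.pk, "crossover")
    assert np.max(np.abs(rows["ddqtcf_ms"])) < 1e-9


def test_zero_noise_chain_is_exactly_linear_in_concentration():
    """With noise off, the derived ddQTcF equals slope*conc exactly at every
    timepoint, so the whole derive/correct/pair chain is verified end to end."""
    slope = 0.0054
    sim = simulate_study(_noise_free(slope, seed=22))
    rows, _ = derive_model_rows(sim.ecg, sim.pk, "crossover")
    drug = rows[rows["treatment"] != "moxifloxacin"]
    np.testing.assert_allclose(drug["ddqtcf_ms"], slope * drug["conc"], atol=1e-9)


def test_simulated_study_recovers_theta_through_full_fit():
    """One mid-size replicate: the fitted slope lands within a few standard
    errors of the generating 0.0054 ms/(ng/mL)."""
    sim = simulate_study(tqt_reference(seed=30))
    rows, _ = derive_model_rows(sim.ecg, sim.pk, "crossover")
    drug = rows[rows["treatment"] != "moxifloxacin"]
    fit = fit_cqtc(drug)
    se = np.sqrt(fit.fixed_cov[1, 1])
    assert abs(fit.theta1 - 0.0054) < 4 * se


def test_pk_iiv_is_lognormal_around_typical_values():
    sim = simulate_study(tqt_reference(seed=2))
    cl = sim.truth["cl_f"]
    assert geometric_summary(cl)["gmean"] == pytest.approx(3.0, rel=0.15)
    assert 10.0 < geometric_summary(cl)["gcv_percent"] < 45.0
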