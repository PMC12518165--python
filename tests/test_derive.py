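import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cqtkit.derive import (
    baseline_adjust,
    derive_intervals,
    fridericia,
    heart_rate,
    pair_concentration,
    placebo_correct_crossover,
    placebo_correct_parallel,
)


def _ecg(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "treatment", "period", "day", "time_h",
                 "qt_ms", "rr_ms"],
    )


@pytest.mark.parametrize("rr,expected", [(1000.0, 60.0), (800.0, 75.0), (500.0, 120.0)])
def test_heart_rate(rr, expected):
    assert heart_rate(rr) == pytest.approx(expected)


def test_heart_rate_rejects_nonpositive():
    with pytest.raises(ValueError):
        heart_rate(0.0)


@pytest.mark.parametrize(
    "qt,rr,expected",
    [(400.0, 1000.0, 400.0),            # RR = 1 s: identity
     (350.0, 729.0, 350.0 / 0.9),       # perfect-cube RR
     (400.0, 800.0, 400.0 / 0.8 ** (1 / 3))],
)
def test_fridericia(qt, rr, expected):
    assert fridericia(qt, rr) == pytest.approx(expected, rel=1e-12)


def test_fridericia_rejects_nonpositive():
    with pytest.raises(ValueError):
        fridericia(400.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    qt=st.floats(200, 500),
    rr1=st.floats(400, 1500),
    rr2=st.floats(400, 1500),
    scale=st.floats(0.5, 2.0),
)
def test_fridericia_monotone_and_homogeneous(qt, rr1, rr2, scale):
    """QTcF strictly decreases in RR at fixed QT, and is homogeneous of
    degree 1 in QT."""
    lo, hi = sorted([rr1, rr2])
    if hi > lo:
        assert fridericia(qt, lo) > fridericia(qt, hi)
    assert fridericia(scale * qt, rr1) == pytest.approx(
        scale * fridericia(qt, rr1), rel=1e-12
    )


def test_baseline_adjust_uses_predose_mean():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.2, 398.0, 1000.0),
        ("S1", "active", 1, 1, -0.1, 402.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 410.0, 1000.0),
        ("S1", "active", 1, 1, 4.0, 400.0, 1000.0),
    ])
    adjusted = baseline_adjust(derive_intervals(ecg))
    post = adjusted[adjusted["time_h"] > 0].set_index("time_h")
    assert post.loc[2.0, "baseline_qtcf_ms"] == pytest.approx(400.0)
    assert post.loc[2.0, "dqtcf_ms"] == pytest.approx(10.0)
    assert post.loc[4.0, "dqtcf_ms"] == pytest.approx(0.0)


def test_baseline_adjust_excludes_subjects_without_predose():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.1, 400.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 410.0, 1000.0),
        ("S2", "active", 1, 1, 2.0, 405.0, 1000.0),  # no baseline
    ])
    adjusted = baseline_adjust(derive_intervals(ecg))
    assert set(adjusted["subject_id"]) == {"S1"}


def test_crossover_correction_subtracts_time_matched_placebo():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.1, 400.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 405.0, 1000.0),
        ("S1", "active", 1, 1, 12.0, 404.0, 1000.0),
        ("S1", "placebo", 2, 1, -0.1, 400.0, 1000.0),
        ("S1", "placebo", 2, 1, 2.0, 402.0, 1000.0),  # no 12 h placebo record
    ])
    adjusted = baseline_adjust(derive_intervals(ecg))
    rows, acct = placebo_correct_crossover(adjusted)
    assert len(rows) == 1
    assert rows.iloc[0]["ddqtcf_ms"] == pytest.approx(3.0)
    assert acct["n_dropped_no_placebo_match"] == 1
    assert acct["n_rows"] + acct["n_dropped_no_placebo_match"] == acct["n_active_rows"]


def test_crossover_identical_arms_give_zero_ddqtcf():
    """Active and placebo arms that are copies yield ddQTcF identically 0."""
    template = [(-0.1, 400.0), (1.0, 403.0), (2.0, 407.0), (4.0, 402.0)]
    recs = []
    for trt, period in [("active", 1), ("placebo", 2)]:
        for t, qt in template:
            recs.append(("S1", trt, period, 1, t, qt, 1000.0))
    rows, _ = placebo_correct_crossover(baseline_adjust(derive_intervals(_ecg(recs))))
    assert np.allclose(rows["ddqtcf_ms"], 0.0, atol=1e-12)


def test_crossover_subject_without_placebo_dropped():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.1, 400.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 405.0, 1000.0),
    ])
    rows, acct = placebo_correct_crossover(baseline_adjust(derive_intervals(ecg)))
    assert rows.empty
    assert acct["subjects_without_placebo"] == ["S1"]


def test_parallel_correction_uses_pooled_placebo_mean():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.1, 400.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 404.0, 1000.0),   # dqtcf 4
        ("S2", "placebo", 1, 1, -0.1, 400.0, 1000.0),
        ("S2", "placebo", 1, 1, 2.0, 401.0, 1000.0),  # dqtcf 1
        ("S3", "placebo", 1, 1, -0.1, 400.0, 1000.0),
        ("S3", "placebo", 1, 1, 2.0, 403.0, 1000.0),  # dqtcf 3
    ])
    rows, _ = placebo_correct_parallel(baseline_adjust(derive_intervals(ecg)))
    assert rows.iloc[0]["ddqtcf_ms"] == pytest.approx(2.0)


def test_parallel_requires_placebo_arm():
    ecg = _ecg([
        ("S1", "active", 1, 1, -0.1, 400.0, 1000.0),
        ("S1", "active", 1, 1, 2.0, 404.0, 1000.0),
    ])
    with pytest.raises(ValueError, match="placebo"):
        placebo_correct_parallel(baseline_adjust(derive_intervals(ecg)))


def test_pair_concentration_matching_and_drops():
    rows = pd.DataFrame({
        "subject_id": ["S1", "S1", "S1"],
        "treatment": ["active"] * 3,
        "period": [1, 1, 1],
        "day": [1, 1, 1],
        "time_h": [2.0, 5.0, -0.1],
        "ddqtcf_ms": [3.0, 2.0, 0.0],
        "ddhr_bpm": [0.0, 0.0, 0.0],
        "baseline_qtcf_ms": [400.0] * 3,
    })
    pk = pd.DataFrame({
        "subject_id": ["S1"], "treatment": ["active"], "period": [1],
        "day": [1], "time_h": [2.0], "analyte": ["drug"], "conc": [150.0],
    })
    paired, acct = pair_concentration(rows, pk)
    assert acct["n_dropped_no_conc_match"] == 1  # 5 h row has no PK sample
    by_time = paired.set_index("time_h")["conc"]
    assert by_time[2.0] == 150.0
    assert by_time[-0.1] == 0.0  # pre-dose rows carry conc 0


def test_row_accounting_on_simulated_study(tqt_rows_small, tqt_sim_small):
    """|model rows| + dropped == |eligible active-arm post-dose records|."""
    rows, acct = tqt_rows_small
    ecg = tqt_sim_small.ecg
    eligible = ecg[(ecg["treatment"] != "placebo") & (ecg["time_h"] > 0)]
    total_dropped = (acct["n_dropped_no_placebo_match"]
                     + acct["n_dropped_no_conc_match"])
    assert len(rows) + total_dropped == len(eligible)
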