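import numpy as np
import pandas as pd
import pytest

from cqtkit.pipeline import derive_model_rows
from cqtkit.simulate import simulate_study, tqt_reference


@pytest.fixture(scope="session")
def tqt_sim_small():
    """A small (n = 8) simulated crossover thorough-QT study."""
    return simulate_study(tqt_reference(seed=7, n_subjects=8))


@pytest.fixture(scope="session")
def tqt_rows_small(tqt_sim_small):
    rows, accounting = derive_model_rows(
        tqt_sim_small.ecg, tqt_sim_small.pk, "crossover"
    )
    return rows, accounting


@pytest.fixture(scope="session")
def drug_rows_small(tqt_rows_small):
    rows, _ = tqt_rows_small
    return rows[rows["treatment"] != "moxifloxacin"]


@pytest.fixture()
def mixed_effects_data():
    """Simulated random-intercept/slope data with known generating values."""
    rng = np.random.default_rng(42)
    n_subj, n_obs = 20, 12
    frames = []
    for i in range(n_subj):
        conc = rng.uniform(0, 400, n_obs)
        baseline = rng.normal(410, 10)
        eta0 = rng.normal(0, 2.0)
        eta1 = rng.normal(0, 0.002)
        y = (1.5 + eta0) + (0.005 + eta1) * conc + rng.normal(0, 3.0, n_obs)
        frames.append(pd.DataFrame({
            "subject_id": f"S{i:02d}", "conc": conc, "ddqtcf_ms": y,
            "baseline_qtcf_ms": baseline,
        }))
    return pd.concat(frames, ignore_index=True)
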