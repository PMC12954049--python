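import numpy as np
import pytest

import oubranch as ob
from oubranch.datasets import dataset_from_arrays


@pytest.fixture(scope="session")
def wt_params():
    return ob.OUParams(mu=-6.799, theta=0.775, sigma=0.727)


@pytest.fixture(scope="session")
def pria_params():
    return ob.OUParams(mu=-5.000, theta=0.117, sigma=0.436)


@pytest.fixture(scope="session")
def recg_params():
    return ob.OUParams(mu=-7.652, theta=8.516, sigma=2.789)


@pytest.fixture(scope="session")
def panel():
    """Default synthetic 3-lineage panel plus its ground-truth record."""
    table, truth = ob.generate_panel(ob.SyntheticPanelSpec(seed=0))
    return table, truth


@pytest.fixture(scope="session")
def panel_datasets(panel):
    table, _ = panel
    return {lin: ob.floor_and_log(table, lin) for lin in ("WT", "priA", "recG")}


@pytest.fixture(scope="session")
def dense_dataset():
    """Long, densely sampled replicate set with known parameters (dt = 1)."""
    truth = ob.OUParams(mu=-6.8, theta=0.8, sigma=0.7)
    times = np.arange(200.0)
    sims = ob.simulate_exact(truth, truth.mu, times, n_reps=6, seed=7)
    return dataset_from_arrays("dense", times, list(sims)), truth


@pytest.fixture(scope="session")
def dense_fit(dense_dataset):
    data, _ = dense_dataset
    return ob.fit_mle(data, seed=1)


@pytest.fixture(scope="session")
def toy_dataset():
    """Two-replicate toy series small enough for hand-checking."""
    return dataset_from_arrays(
        "toy",
        np.array([0.0, 1.0, 2.5]),
        [np.array([1.0, 0.5, 0.2]), np.array([0.3, 0.1, -0.4])],
    )
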