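import numpy as np
import pandas as pd
import pytest

import methvar as mv
from methvar import preprocess as pp
from methvar import variability as vb


@pytest.fixture(scope="session")
def small_config():
    return mv.SimulationConfig(n_islands=400, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mv.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    cfg = small_dataset.config
    sm = pp.SignalMatrix(small_dataset.signals, small_dataset.design)
    norm, report = pp.normalize_signal_matrix(
        sm, small_dataset.intensity, cfg.background_mean, cfg.background_sd)
    return norm, report


def make_signal_matrix(values, groups):
    """SignalMatrix from a plain array and one group label per column."""
    values = np.asarray(values, dtype=float)
    cols = [f"a{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])],
                      columns=cols)
    design = pd.DataFrame({"array_id": cols, "group": groups})
    return pp.SignalMatrix(values=df, design=design)


@pytest.fixture(scope="session")
def null_signal_matrix():
    """1000 probes x 2 groups of 5 arrays, equal-variance Gaussian null."""
    rng = np.random.default_rng(123)
    return make_signal_matrix(rng.normal(0, 1, (1000, 10)),
                              ["A"] * 5 + ["B"] * 5)
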