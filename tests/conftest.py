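import numpy as np
import pandas as pd
import pytest

from intergen import Design, SynthConfig, generate_count_experiment


@pytest.fixture(scope="session")
def design() -> Design:
    return Design.default()


@pytest.fixture(scope="session")
def small_experiment(design):
    """A small synthetic count experiment shared across read-only tests."""
    cfg = SynthConfig(n_contigs=400, seed=101)
    return generate_count_experiment(cfg, design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def gaussian_matrix(design: Design, n_rows: int, seed: int, group_sd=None) -> pd.DataFrame:
    """Normal expression matrix with optional per-group standard deviations."""
    r = np.random.default_rng(seed)
    cols = {}
    for s in design.samples:
        sd = 1.0 if group_sd is None else group_sd[design.group_of(s)]
        cols[s] = r.normal(0.0, sd, n_rows)
    return pd.DataFrame(cols, index=[f"c{i:05d}" for i in range(n_rows)])
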