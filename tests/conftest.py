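import numpy as np
import pandas as pd
import pytest

from dielphase import SimConfig, TraceSet, gen_diel_matrix


def make_traceset(t: np.ndarray, Y: np.ndarray) -> TraceSet:
    """Assemble a TraceSet from a shared grid t and per-cell columns of Y."""
    n, m = Y.shape
    ids = np.repeat([f"c{k:04d}" for k in range(m)], n)
    data = pd.DataFrame(
        {"cell_id": ids, "time_h": np.tile(t, m), "fluorescence": Y.T.ravel()}
    )
    return TraceSet(data=data)


@pytest.fixture
def small_noiseless():
    """20-gene noiseless planted matrix with its truth table."""
    cfg = SimConfig(
        seed=7, n_genes_per_class={"I": 10, "II": 5, "NC": 5}, noise_sd_log2=0.0
    )
    return gen_diel_matrix(cfg, mode="wt")


@pytest.fixture
def small_noisy():
    cfg = SimConfig(
        seed=11, n_genes_per_class={"I": 200, "II": 60, "NC": 40}, noise_sd_log2=0.25
    )
    return gen_diel_matrix(cfg, mode="wt")
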