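import numpy as np
import pytest

import scmomtf as sm


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset: 400 cells, 5 types, 120 genes + 80 peaks."""
    cfg = sm.SimulationConfig(
        n_cells=400, n_types=5, n_rna=120, n_atac=80, n_markers_per_type=8,
        marker_fold_change=4.0, seed=11,
    )
    return sm.generate_paired_dataset(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    ds, gt = small_dataset
    return sm.normalize_counts(ds), gt


@pytest.fixture(scope="session")
def trained_small(small_normalized):
    """Model trained for 40 epochs on the small dataset (seconds of CPU)."""
    ds, gt = small_normalized
    state, log = sm.train(ds, tcfg=sm.TrainConfig(epochs=40, batch_size=128, seed=3))
    return state, log, ds, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
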