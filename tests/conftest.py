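import numpy as np
import pandas as pd
import pytest

from scdose import CellAnnotations, CountMatrix, SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """5 genes x 5 cells with one all-zero gene."""
    values = np.array([
        [5, 0, 2, 1, 3],
        [0, 0, 0, 0, 0],
        [1, 1, 1, 1, 1],
        [0, 4, 0, 0, 0],
        [2, 2, 0, 7, 1],
    ])
    return CountMatrix(values, [f"g{i}" for i in range(5)],
                       [f"c{j}" for j in range(5)])


@pytest.fixture
def small_annotations():
    def make(cell_ids, n_scr):
        n = len(cell_ids)
        return CellAnnotations(pd.DataFrame({
            "cell_id": cell_ids,
            "treatment": ["SCR"] * n_scr + ["siTARGET"] * (n - n_scr),
            "batch": ["B1"] * (n_scr // 2) + ["B2"] * (n_scr - n_scr // 2)
                     + ["B3"] * (n - n_scr),
        }))
    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated knockdown dataset shared across tests."""
    cfg = SimulationConfig(n_genes=300, n_scr=20, n_detectable=10,
                           n_undetectable=12, frac_de=0.2, seed=42)
    return generate_dataset(cfg)
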