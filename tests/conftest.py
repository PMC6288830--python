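import numpy as np
import pytest

from mtmepred import GRM, MTMEDataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A complete J=10, I=2, L=2 dataset with its generating truth."""
    ds, truth = simulate_dataset(SimulationConfig(J=10, I=2, L=2, p=60, seed=42))
    return ds, truth


@pytest.fixture()
def toy_dataset():
    """Tiny hand-indexable dataset: 3 lines, 2 environments, 2 traits."""
    rng = np.random.default_rng(7)
    line_ids = ["A", "B", "C"]
    env_ids = ["E1", "E2"]
    G = GRM(np.array([[1.0, 0.5, 0.2],
                      [0.5, 1.0, 0.3],
                      [0.2, 0.3, 1.0]]), line_ids)
    cells = [(l, e) for e in env_ids for l in line_ids]
    Y = rng.standard_normal((6, 2))
    return MTMEDataset(cells, Y, env_ids, ["T1", "T2"], G, line_ids)
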