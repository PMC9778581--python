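import numpy as np
import pandas as pd
import pytest

import gkblup as gk


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded J=30, 2-environment dataset with moderate bandwidth."""
    cfg = gk.SimulationConfig(J=30, p=80, I=2, rho_true=0.2, seed=11)
    return gk.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_kernel(small_dataset):
    dist = gk.squared_distance_matrix(small_dataset.markers)
    return gk.gaussian_kernel(dist, 0.2)


@pytest.fixture
def toy_markers():
    G = np.array([
        [0, 1, 2, 0, 1],
        [2, 1, 0, 1, 0],
        [1, 0, 1, 2, 2],
        [0, 2, 2, 1, 1],
    ], dtype=float)
    return gk.MarkerMatrix(line_ids=["a", "b", "c", "d"], G=G)


def make_phenotypes(lines, envs, values=None):
    rows = []
    k = 0
    for e in envs:
        for l in lines:
            v = 1.0 * k if values is None else values[k]
            rows.append({"line": l, "env": e, "value": v})
            k += 1
    return pd.DataFrame(rows)
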