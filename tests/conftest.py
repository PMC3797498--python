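import numpy as np
import pandas as pd
import pytest

from ecoassembly import CommunityMatrix, EnvironmentTable, PlotCoordinates


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_community():
    """Four plots, three species, hand-checkable."""
    frame = pd.DataFrame(
        [[6, 2, 0], [2, 6, 0], [0, 0, 8], [3, 3, 2]],
        index=["p1", "p2", "p3", "p4"],
        columns=["sp1", "sp2", "sp3"],
    )
    return CommunityMatrix(frame)


def random_community(rng, n_plots=10, n_species=20, mean_total=100):
    """Neutral multinomial community used across tests."""
    base = rng.lognormal(0, 1, n_species)
    p = base / base.sum()
    totals = np.maximum(rng.poisson(mean_total, n_plots), 1)
    counts = np.vstack([rng.multinomial(t, p) for t in totals])
    counts = counts[:, counts.sum(axis=0) > 0]
    frame = pd.DataFrame(
        counts,
        index=[f"p{i}" for i in range(n_plots)],
        columns=[f"s{i}" for i in range(counts.shape[1])],
    )
    return CommunityMatrix(frame)


@pytest.fixture
def transect_coords():
    x = np.linspace(0.0, 9000.0, 10)
    return PlotCoordinates(tuple(f"p{i}" for i in range(10)), x, np.zeros(10))


@pytest.fixture
def env_table(rng):
    frame = pd.DataFrame(
        rng.standard_normal((10, 4)),
        index=[f"p{i}" for i in range(10)],
        columns=["elevation", "ph", "som", "slope"],
    )
    return EnvironmentTable(frame)
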