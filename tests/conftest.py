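import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mtdrift.fitness import SuppressivityGrid
from mtdrift.sim import SimulationParams

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_params():
    """Small, short simulation: enough for ~2 division rounds."""
    return SimulationParams(n_cells_init=50, t_total_min=300.0, seed=7)


def make_toy_grid(rows):
    """SuppressivityGrid from explicit (h0, fitness, suppressivity) rows."""
    df = pd.DataFrame(rows, columns=["h0", "fitness", "suppressivity"])
    df["rep"] = 0
    df["seed"] = 0
    f = df["fitness"]
    return SuppressivityGrid(
        replicates=df[["h0", "fitness", "rep", "seed", "suppressivity"]],
        params_used=SimulationParams(),
        fitness_range_used=(float(f.min()), float(f.max())),
    )


@pytest.fixture
def toy_grid():
    """Dense deterministic toy grid: suppressivity = clip(h0 * fitness, 0, 1)."""
    rows = [
        (h, f, min(1.0, h * f))
        for h in np.linspace(0, 1, 11)
        for f in np.linspace(0, 2, 11)
    ]
    return make_toy_grid(rows)
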