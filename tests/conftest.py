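import numpy as np
import pandas as pd
import pytest

from capdyn import SimulationConfig, simulate_population


def make_records(counts, weights=None, time=1, site="s1"):
    """Capture records with given per-category counts (n1, n2, n3)."""
    n1, n2, n3 = counts
    hist = [(1, 0)] * n1 + [(0, 1)] * n2 + [(1, 1)] * n3
    n = len(hist)
    rng = np.random.default_rng(0)
    if weights is None:
        weights = rng.lognormal(0, 0.3, n)
    return pd.DataFrame(
        {
            "id": [f"i{j}" for j in range(n)],
            "site": site,
            "time": time,
            "w1": [h[0] for h in hist],
            "w2": [h[1] for h in hist],
            "weight": weights,
        }
    )


@pytest.fixture
def petersen_records():
    return make_records((20, 30, 50))


@pytest.fixture(scope="session")
def sim_pop():
    """One reference simulated series (moderate process variance)."""
    cfg = SimulationConfig(phi1=0.5, phi2=-0.2, sigma2_eps=0.08)
    return simulate_population(cfg, 424242)


@pytest.fixture(scope="session")
def heterogeneous_records():
    """~350 captured individuals with a weight covariate, truth attached."""
    cfg = SimulationConfig(phi1=0.5, phi2=-0.2, sigma2_eps=0.08)
    pop = simulate_population(cfg, 91)
    return pop.observed(), cfg
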