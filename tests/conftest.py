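import numpy as np
import pandas as pd
import pytest

from forestnets import (CrownDistribution, NullModelConfig, Window,
                        assign_crown_radii, simulate_csr)


@pytest.fixture(scope="session")
def window() -> Window:
    return Window(0.0, 200.0, 0.0, 200.0)


@pytest.fixture(scope="session")
def small_window() -> Window:
    return Window(0.0, 50.0, 0.0, 50.0)


@pytest.fixture(scope="session")
def csr_pattern(window):
    """One labelled CSR pattern at the default intensity."""
    pat = simulate_csr(NullModelConfig(model="CSR"), window, seed=42)
    return assign_crown_radii(pat, CrownDistribution(), seed=43)


@pytest.fixture()
def three_tree_table() -> pd.DataFrame:
    """Collinear trees at x = 0, 8, 16 m with known crown radii."""
    return pd.DataFrame({
        "id": ["a", "b", "c"],
        "x": [0.0, 8.0, 16.0],
        "y": [0.0, 0.0, 0.0],
        "crown_radius": [3.0, 2.0, 4.0],
    })


def random_tree_table(rng: np.random.Generator, n: int, side: float = 60.0,
                      crown_lo: float = 2.0, crown_hi: float = 5.0) -> pd.DataFrame:
    return pd.DataFrame({
        "id": np.arange(n),
        "x": rng.uniform(0, side, n),
        "y": rng.uniform(0, side, n),
        "crown_radius": rng.uniform(crown_lo, crown_hi, n),
    })
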