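import numpy as np
import pandas as pd
import pytest

from sociophylo import synthetic_data as sd
from sociophylo.treeio import read_newick


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):0.5,C:1.5) — the worked covariance example."""
    return read_newick("((A:1,B:1):0.5,C:1.5):0;")


@pytest.fixture(scope="session")
def yule100():
    return sd.simulate_yule_tree(100, 1.0, seed=11)


@pytest.fixture(scope="session")
def yule300():
    return sd.simulate_yule_tree(300, 1.0, seed=7)


@pytest.fixture(scope="session")
def trait_table():
    rng = np.random.default_rng(5)
    n = 40
    states = []
    for i in range(n):
        r = rng.random()
        if r < 0.5:
            states.append("solitary")
        elif r < 0.7:
            states.append("pair-living")
        elif r < 0.9:
            states.append("group-living")
        else:
            states.append("solitary;group-living")
    return pd.DataFrame({
        "species": [f"sp{i:04d}" for i in range(n)],
        "social_states": states,
        "lifespan": rng.lognormal(3.0, 0.5, n).round(1),
        "body_mass": rng.lognormal(8.0, 2.0, n).round(1),
        "activity": rng.choice(["diurnal", "nocturnal"], n),
        "diet": rng.choice(["herbivore", "carnivore", "omnivore"], n),
        "lifestyle": rng.choice(["terrestrial", "arboreal", "aerial"], n),
        "fossoriality": rng.choice(["yes", "no"], n),
    })
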