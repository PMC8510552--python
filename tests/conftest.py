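import numpy as np
import pandas as pd
import pytest

from assemblage import (OtuTable, SampleMetadata, SyntheticDesign,
                        patristic_distances, simulate_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        [[10, 0, 3, 1], [2, 5, 0, 1], [0, 8, 4, 0]],
        index=["s1", "s2", "s3"], columns=["o1", "o2", "o3", "o4"])
    return OtuTable(df)


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 40, size=(8, 12))
    df = pd.DataFrame(counts, index=[f"s{i}" for i in range(8)],
                      columns=[f"o{j}" for j in range(12)])
    return OtuTable(df)


@pytest.fixture(scope="session")
def tree20():
    return simulate_tree(20, seed=7)


@pytest.fixture(scope="session")
def pdm20(tree20):
    return patristic_distances(tree20)


@pytest.fixture
def tiny_metadata():
    df = pd.DataFrame({
        "station": ["ST1", "ST1", "ST2", "ST2"],
        "habitat_class": ["nearshore", "nearshore", "offshore", "offshore"],
        "layer": ["surface", "surface", "surface", "surface"],
        "latitude": [22.0, 22.0, 18.0, 18.0],
        "longitude": [114.5, 114.5, 116.0, 116.0],
        "depth": [5.0, 5.0, 5.0, 5.0],
        "temperature": [20.0, 21.0, 28.0, 29.0],
        "salinity": [33.0, 33.1, 34.0, 34.1],
        "dissolved_oxygen": [7.0, 7.1, 6.0, 6.1],
        "bacterial_abundance": [1e6, 1.1e6, 2e6, 2.1e6],
    }, index=["a1", "a2", "b1", "b2"])
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def default_design():
    return SyntheticDesign()
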