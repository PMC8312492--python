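import numpy as np
import pandas as pd
import pytest

from reefpipe import simulate


@pytest.fixture(scope="session")
def taxonomy() -> pd.DataFrame:
    return simulate.default_taxonomy()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benthic_config(taxonomy) -> simulate.BenthicSimConfig:
    """Two areas, two sites each, two surveys — small but full-depth photos."""
    base = np.full(len(taxonomy), 2.0)
    shifted = base.copy()
    shifted[0] = 8.0  # one dominant OTU boosted in the second area
    return simulate.BenthicSimConfig(
        taxonomy=taxonomy,
        compositions={"west_coast": base, "east_coast": shifted},
        sites={"west_coast": ["w1", "w2"], "east_coast": ["e1", "e2"]},
        surveys=("s1", "s2"),
        transects=2,
        photos=10,
        points_per_photo=50,
    )


@pytest.fixture(scope="session")
def small_records(small_benthic_config):
    records, manifest = simulate.simulate_benthic(small_benthic_config, seed=7)
    return records, manifest
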