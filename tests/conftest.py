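import numpy as np
import pytest

from wellnet import synthetic, tables
from wellnet.pipeline import plant_pairs


@pytest.fixture(scope="session")
def community() -> synthetic.SourceCommunity:
    return synthetic.simulate_source(20, lognormal_sigma=1.0, cells_per_ul=1e6, seed=7)


@pytest.fixture(scope="session")
def planted_truth(community) -> synthetic.InteractionTruth:
    return plant_pairs(community, n_pairs=2, sign=1, effect=2.5, reference_dilution=4)


@pytest.fixture(scope="session")
def design() -> tables.PlateDesign:
    return tables.PlateDesign(sample_type="roots", medium="R2A", dilution_level=4, replicate="A")


@pytest.fixture(scope="session")
def simulated_plate(community, planted_truth, design) -> tables.PlateTable:
    plate, _ = synthetic.simulate_plate(community, planted_truth, design, read_depth=5000, seed=11)
    return plate


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_19_11_05)
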