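import numpy as np
import pytest

from paleoploid.collinearity import CollinearityParams, detect_blocks, filter_families
from paleoploid.simulate import fractionation_scenario, simulate_dataset


@pytest.fixture(scope="session")
def wgd_dataset():
    """Single WGD at retention 0.5 against an outgroup reference."""
    return simulate_dataset(fractionation_scenario(seed=3, retention=0.5))


@pytest.fixture(scope="session")
def wgd_blocks(wgd_dataset):
    ds = wgd_dataset
    pairs = filter_families(ds.pairs[("focal", "reference")])
    return detect_blocks(pairs, ds.gene_sets["reference"],
                         ds.gene_sets["focal"], CollinearityParams())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
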