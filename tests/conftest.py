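import numpy as np
import pytest

from orthosim import SimulationConfig
from orthosim.synthetic_data import generate_dataset, simulate_triplets


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_triplets():
    """20 simulated genes (length 300) with the mouse branch at 2x the
    rabbit branch's substitution probability."""
    config = SimulationConfig(
        n_genes=20, length_min=300, length_max=300,
        sub_prob_rabbit=0.05, sub_prob_mouse=0.10, seed=11,
    )
    records, truths = simulate_triplets(config)
    return config, records, truths


@pytest.fixture
def fixture_dir(tmp_path):
    """A small on-disk simulated dataset with decoy X2 isoforms."""
    config = SimulationConfig(
        n_genes=5, length_min=300, length_max=360,
        sub_prob_rabbit=0.05, sub_prob_mouse=0.10,
        decoy_isoforms=True, seed=3,
    )
    directory = tmp_path / "dataset"
    manifest = generate_dataset(config, directory)
    return config, directory, manifest


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
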