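import numpy as np
import pytest

from cellosim import readsim as rs
from cellosim import reference as ref


@pytest.fixture(scope="session")
def small_family():
    """Six 3 kb copies (divergence grid 5-200 milliDiv) in a 60 kb genome."""
    spec = ref.RepeatFamilySpec(
        ancestral_length=3000,
        copy_number=6,
        genome_length=60_000,
        divergence_grid=(5.0, 20.0, 80.0, 200.0),
        seed=1,
    )
    return ref.plant_copies(spec)


@pytest.fixture(scope="session")
def perfect_reads(small_family):
    genome, anns = small_family
    config = rs.SimulationConfig(identity_mode="perfect", coverage=1, seed=3)
    reads, truth = rs.simulate_arm(anns, genome, config)
    return reads, truth, config


@pytest.fixture(scope="session")
def ont_reads(small_family):
    genome, anns = small_family
    config = rs.SimulationConfig(identity_mode="ont", coverage=5, seed=4)
    reads, truth = rs.simulate_arm(anns, genome, config)
    return reads, truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
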