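import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from haploweb.seq_core import Alignment, Marker, Sequence
from haploweb.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic study, shared across tests."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture
def toy_alignment():
    return Alignment(
        [
            Sequence("s1", "ACGTACGTA", Marker.COI),
            Sequence("s2", "ACGTACGTA", Marker.COI),
            Sequence("s3", "ACGAACGTA", Marker.COI),
        ]
    )
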