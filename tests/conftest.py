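import pytest
from hypothesis import settings

from chiapet.synth import SynthConfig, default_linkers, generate_mapped_pets, generate_pet_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def linkers():
    return default_linkers("short")


@pytest.fixture(scope="session")
def long_linkers():
    return default_linkers("long")


@pytest.fixture(scope="session")
def coord_library():
    """Coordinate-level library: (pets, truth ledger, context)."""
    config = SynthConfig(seed=101, n_molecules=3000)
    return generate_mapped_pets(config)


@pytest.fixture(scope="session")
def read_library():
    """Read-level library small enough for alignment-based tests."""
    config = SynthConfig(seed=102, n_molecules=500, chrom_length=250_000)
    pairs, truth, ctx = generate_pet_library(config)
    return pairs, truth, ctx
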