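import numpy as np
import pytest

from strobeseed import SeedSpec
from strobeseed.simulate import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def seq500():
    """A fixed 500-nt uniform random sequence shared across tests."""
    return random_sequence(500, 42, "seq500")


def standard_specs():
    """One spec per construct at the paper-style (30,64) parameterization."""
    return [
        SeedSpec.kmer(30),
        SeedSpec.spaced("dense"),
        SeedSpec.spaced("sparse"),
        SeedSpec.minstrobes(2, 15, 25, 50),
        SeedSpec.hybridstrobes(15, 25, 50),
        SeedSpec.randstrobes(2, 15, 25, 50),
        SeedSpec.mixedstrobes(15, 25, 50, 0.8),
        SeedSpec.altstrobes(10, 20, 25, 50),
        SeedSpec.multistrobes(5, 25, 25, 50),
    ]


def small_uncorrelated_specs():
    """Small (c,w) specs of the constructs the entropy model supports.

    k_s = 4 for the variable-length constructs: below that the 4^k_s
    distinct codes cannot populate the length/order classes uniformly, so
    the uniform-hash model is documentedly inexact.
    """
    return [
        SeedSpec.randstrobes(2, 5, 10, 16),
        SeedSpec.mixedstrobes(5, 10, 16, 0.5),
        SeedSpec.altstrobes(4, 8, 6, 12),
        SeedSpec.multistrobes(4, 8, 6, 12),
    ]
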