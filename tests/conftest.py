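"""Shared fixtures: one seed-fixed infection-style library reused across tests."""

import numpy as np
import pytest

from evepirna.align import align_reads
from evepirna.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def infection_library():
    """Virus + EVE + mixed siRNA/primary/secondary read populations."""
    conf = SimulationConfig(seed=7, n_sirna=1000, n_primary=2000, n_secondary=2000)
    truth, reads, stats = simulate(conf)
    return conf, truth, reads, stats


@pytest.fixture(scope="session")
def virus_alignments(infection_library):
    """The library aligned to the virus genome at one mismatch."""
    _, truth, reads, _ = infection_library
    return align_reads(reads, truth.virus, max_mismatch=1, k=12)


@pytest.fixture(scope="session")
def reads_by_id(infection_library):
    _, _, reads, _ = infection_library
    return {r.id: r for r in reads}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
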