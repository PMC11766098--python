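import numpy as np
import pytest
from hypothesis import settings

from digiscaff import synthgen
from digiscaff.queries import extract_ranked_queries

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """A 120 kb repeat-free background genome."""
    ref, truth = synthgen.simulate_genome(120_000, seed=5)
    return ref, truth


@pytest.fixture(scope="session")
def tiled_assembly(small_genome):
    """Contigs tiling the genome with 2 kb overlaps, no duplicates, plus
    abutting 1 kb ranked queries — the clean parameter-recovery setting."""
    ref, _ = small_genome
    contigs, truth = synthgen.fragment_into_contigs(
        ref, n_contigs=8, overlap=2000, dup_rate=0.0, seed=6
    )
    queries = extract_ranked_queries(ref, fragment_len=1000, spacing=0)
    return ref, contigs, truth, queries


@pytest.fixture(scope="session")
def repeat_genome():
    """A genome with one dispersed 2 kb repeat family (5 copies)."""
    return synthgen.simulate_genome(
        150_000, [synthgen.RepeatFamily(2000, 5, dispersion=1)], seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
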