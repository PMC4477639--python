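import pytest

from hlacall.mapping import MappingIndex
from hlacall.simulate import SimReferenceConfig, simulate_reference


@pytest.fixture(scope="session")
def small_reference():
    """Two loci x six alleles, ~1 kb cDNAs: small enough for brute-force oracles."""
    ref, truth = simulate_reference(
        SimReferenceConfig(n_loci=2, alleles_per_locus=6, n_exons=4, seed=11)
    )
    return ref, truth


@pytest.fixture(scope="session")
def small_index(small_reference):
    ref, _ = small_reference
    return MappingIndex(ref)
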