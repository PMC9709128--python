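import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sigbloom import (
    CommunitySpec,
    build_index,
    generate_community,
)


@pytest.fixture(scope="session")
def small_community():
    """Five random 2 kb genomes, the standard desk-scale community."""
    return generate_community(CommunitySpec.uniform(5, 2000, seed=11))


@pytest.fixture(scope="session")
def small_index(small_community):
    """Two-phase index over the small community (no thinning)."""
    return build_index(
        small_community, m=2**16, n=2, k=31, phases=2, omega=0, master_seed=11
    )


@pytest.fixture(scope="session")
def single_hash_index(small_community):
    """n=1 index, where classification equals the brute-force oracle exactly."""
    return build_index(
        small_community, m=2**16, n=1, k=31, phases=2, omega=0, master_seed=11
    )
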