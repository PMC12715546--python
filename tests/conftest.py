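import numpy as np
import pytest

from rampsim import (
    SimulationConfig,
    ToyCommunitySpec,
    make_toy_community,
    parse_candidate_sites,
)


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """A small 3-genome community with off-target sites on both strands."""
    spec = ToyCommunitySpec(seed=42, offtargets_per_bait=1, offtarget_mismatches=5)
    return make_toy_community(spec, tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def toy_sites(toy):
    return parse_candidate_sites(toy.sam_path, toy.baits, toy.genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def base_config():
    return SimulationConfig(
        total_fragments=2000,
        capture_fraction=0.8,
        log_mu=6.0,
        log_sigma=0.4,
        seed=7,
        min_fragment_length=50,
    )
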