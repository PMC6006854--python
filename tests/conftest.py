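import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from mitotrna.comparative_search import RecoverConfig
from mitotrna.synthetic_data import GenomeSpec, SyntheticGenome, make_genome, make_panel


@pytest.fixture(scope="session")
def syn_genome() -> SyntheticGenome:
    """One Type-I synthetic genome with the default 6 identities stripped."""
    return make_genome(GenomeSpec(seed=11))


@pytest.fixture(scope="session")
def syn_panel(syn_genome):
    return make_panel(syn_genome, seed=12)


@pytest.fixture(scope="session")
def synthetic_recover_cfg() -> RecoverConfig:
    # the synthetic CR is annotated truth, so it masks sequence
    return RecoverConfig(treat_cr_as_gap=False)
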