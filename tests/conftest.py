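import pytest
from hypothesis import HealthCheck, settings

from alnsens.simulate import (FamilySimConfig, simulate_family,
                              random_study_tree as make_study_tree)

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_family():
    """One desk-scale simulated family shared across tests (9 taxa)."""
    return simulate_family(FamilySimConfig(
        seed=11, n_conserved=5, n_expansion=4, n_codons=120,
        target_identity=0.3))


@pytest.fixture(scope="session")
def default_family():
    """One family at the default study conditions (18 taxa, ~20% identity)."""
    return simulate_family(FamilySimConfig(seed=1))
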