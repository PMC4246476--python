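import pytest

from mresscan.energy import load_params
from mresscan.pipeline import seed_groups_from_mirnas
from mresscan.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def nn_params():
    return load_params()


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated study shared by read-only tests."""
    return simulate_bundle(
        SimConfig(seed=11, n_genes=120, n_mirnas=40, n_snps=3000, n_causal=10,
                  n_disease_genes=25)
    )


@pytest.fixture(scope="session")
def small_groups(small_bundle):
    return seed_groups_from_mirnas(small_bundle.mirnas)
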