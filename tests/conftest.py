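import pytest

from ohnolynch.synthetic_data import SimConfig, simulate_all
from ohnolynch.synthetic_reference import (
    analyse_reference_fixture,
    build_reference_fixture,
)


@pytest.fixture(scope="session")
def reference_fixture():
    """The deterministic synthetic reconstruction of the published table structure."""
    return build_reference_fixture()


@pytest.fixture(scope="session")
def reference_results(reference_fixture):
    """Headline quantities recomputed by the pipeline over the reference fixture."""
    return analyse_reference_fixture(reference_fixture)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fully simulated fixture shared by fast tests."""
    cfg = SimConfig(
        seed=11,
        n_genes=400,
        frac_in_families=0.6,
        binder_family_frac=0.4,
        n_background_sites=120,
        contaminant_pool_size=40,
        seq_length=120,
    )
    return simulate_all(cfg)
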