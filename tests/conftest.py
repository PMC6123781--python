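import pytest
from hypothesis import settings

# property tests must replay identically run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dbtlkit.design_space import DesignSpace, Factor, GeneOrderFactor
from dbtlkit.doe import reduce_library
from dbtlkit.presets import (
    pinocembrin_ground_truth,
    pinocembrin_round1_space,
    to_gene_view,
)
from dbtlkit.synthetic import registry_for_space, simulate_titers


@pytest.fixture(scope="session")
def round1_space():
    return pinocembrin_round1_space()


@pytest.fixture(scope="session")
def library16(round1_space):
    return reduce_library(round1_space, n_runs=16)


@pytest.fixture(scope="session")
def gene_view_lib(library16):
    return to_gene_view(library16)


@pytest.fixture(scope="session")
def registry(round1_space):
    return registry_for_space(round1_space, seed=20240917)


@pytest.fixture(scope="session")
def measurements(gene_view_lib):
    truth = pinocembrin_ground_truth(seed=42)
    return simulate_titers(gene_view_lib, truth)


@pytest.fixture
def tiny_space():
    """Two factors (2 and 3 levels) x 2 fixed-ish genes: 6 x 2 = 12 points."""
    return DesignSpace(
        factors=(
            Factor("a", ("a1", "a2")),
            Factor("b", ("b1", "b2", "b3")),
        ),
        order_factor=GeneOrderFactor(("g1", "g2")),
    )
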