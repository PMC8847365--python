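import pytest

from lncquarry.pipeline import run_discovery
from lncquarry.simulate import GeneratorConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """The default synthetic world (seed 17), shared across the suite."""
    return generate_world(GeneratorConfig())


@pytest.fixture(scope="session")
def discovery(world):
    """(catalogue, traces) from one cascade run on the default world."""
    return run_discovery(world.assembled, world.reference, world.genome,
                         world.repeats, world.expression, world.known_lnc_db,
                         world.exclusion_dbs)


@pytest.fixture(scope="session")
def ref_index(world):
    from lncquarry.classify import ReferenceIndex
    return ReferenceIndex(world.reference)
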