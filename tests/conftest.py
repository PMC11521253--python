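import numpy as np
import pytest

from traitdiv import (ScenarioConfig, build_reference_schema, code_traits,
                      generate_species_pool)


@pytest.fixture(scope="session")
def schema():
    return build_reference_schema()


@pytest.fixture(scope="session")
def pool20(schema):
    """20-species coded pool drawn from the generator (fixed seed)."""
    records = generate_species_pool(ScenarioConfig(n_species=20, seed=11), schema)
    return code_traits(records, schema)


@pytest.fixture(scope="session")
def pool100(schema):
    records = generate_species_pool(ScenarioConfig(n_species=100, seed=7), schema)
    return code_traits(records, schema)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
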