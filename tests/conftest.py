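import numpy as np
import pytest

from abcsnp.coalsim import GroupConfig
from abcsnp.scenarios import PriorSpec, Scenario, builtin_scenarios
from abcsnp.synthdata import make_worked_example


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def priors():
    return PriorSpec()


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def single_deme():
    """One-deme scenario (no events) for closed-form coalescent checks."""
    return Scenario(id=99, events=(), demes=("Pop1",), size_symbols=("N1",))


@pytest.fixture(scope="session")
def two_deme():
    """Two demes merging at t1; deme 1 takes the ancestral size above it."""
    from abcsnp.scenarios import DemographicEvent

    return Scenario(
        id=98,
        events=(DemographicEvent(time_symbol="t1", kind="merge", source="Pop2",
                                 dest="Pop1", dest_size_symbol="NA"),),
        demes=("Pop1", "Pop2"),
        size_symbols=("N1", "N2"),
    )


@pytest.fixture(scope="session")
def pair_groups():
    return GroupConfig(("A", "B"), (5, 5))
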