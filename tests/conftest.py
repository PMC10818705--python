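import pytest

from hopmap import (
    ETParameters,
    HoppingSystem,
    load_table2_potentials,
    load_table3_rates,
)


@pytest.fixture(scope="session")
def params() -> ETParameters:
    """Default semiclassical parameters (lambda 0.8 eV, beta 1.1 /A, 298 K)."""
    return ETParameters()


@pytest.fixture(scope="session")
def system() -> HoppingSystem:
    """Default Ru-Tyr109-Cu geometry (16.5 / 18.3 / 34.8 A)."""
    return HoppingSystem()


@pytest.fixture(scope="session")
def table2():
    return load_table2_potentials()


@pytest.fixture(scope="session")
def table3():
    return load_table3_rates()
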