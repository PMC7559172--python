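import pytest

from prognet import bundled_table1, effects_from_records


@pytest.fixture(scope="session")
def table1():
    """The bundled 11-cohort miR-203 / CRC overall-survival table."""
    return bundled_table1()


@pytest.fixture(scope="session")
def table1_effects(table1):
    return effects_from_records(table1)
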