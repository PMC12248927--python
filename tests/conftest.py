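import pytest
from hypothesis import HealthCheck, settings

from feedlot_econ.production_data import (
    DietName,
    EconParams,
    PPClass,
    builtin_table1,
    builtin_table2,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The nine built-in study cohorts."""
    return builtin_table1()


@pytest.fixture(scope="session")
def table2_ref():
    """Printed reference economics, row letter -> (pp, diet) -> value."""
    return builtin_table2()


@pytest.fixture(scope="session")
def params():
    """Study economic parameters (all defaults)."""
    return EconParams()


@pytest.fixture(scope="session")
def cohort_of(table1):
    """Lookup helper: cohort_of('PP2', 'MPD')."""
    index = {c.key: c for c in table1}

    def _get(pp: str, diet: str):
        return index[(PPClass.parse(pp), DietName(diet))]

    return _get
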