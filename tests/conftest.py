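import pytest

from osas_cea import default_parameters


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture()
def immortal_params(base_params):
    """Base case with an all-zero life table (no background mortality)."""
    from osas_cea import LifeTable

    return base_params.with_overrides(
        life_table=LifeTable(start_age=50, annual_death_prob=(0.0,) * 5)
    )
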