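import pytest

from afcea import fixtures


@pytest.fixture(scope="session")
def base_params():
    return fixtures.base_case()


@pytest.fixture(scope="session")
def no_event_params():
    return fixtures.make_fixture("no_events")


@pytest.fixture(scope="session")
def null_effect_params():
    return fixtures.make_fixture("null_effect")
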