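import pytest

from monofilm import make_study_registry, study_records


@pytest.fixture(scope="session")
def registry_and_subphase():
    return make_study_registry()


@pytest.fixture(scope="session")
def registry(registry_and_subphase):
    return registry_and_subphase[0]


@pytest.fixture(scope="session")
def subphase(registry_and_subphase):
    return registry_and_subphase[1]


@pytest.fixture(scope="session")
def records():
    """Forward-analyzed records for the eleven study films."""
    return study_records()


@pytest.fixture(scope="session")
def records_by_name(records):
    return {r.label: r for r in records}
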