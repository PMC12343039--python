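import pytest

from loricaballast import builtin_reference, load_fixture


@pytest.fixture(scope="session")
def reference():
    return builtin_reference()


@pytest.fixture(scope="session")
def table2(reference):
    return load_fixture("table2", reference)


@pytest.fixture(scope="session")
def table4(reference):
    return load_fixture("table4", reference)


@pytest.fixture(scope="session")
def all_fixtures(reference):
    from loricaballast import FIXTURE_NAMES

    return {name: load_fixture(name, reference) for name in FIXTURE_NAMES}
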