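import pytest

from stewardbench import GuardrailConfig, default_catalog, run_all, table2_fixture


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def cfg():
    return GuardrailConfig()


@pytest.fixture(scope="session")
def fixture_cohort():
    return table2_fixture()


@pytest.fixture(scope="session")
def fixture_bundle(fixture_cohort):
    """The full endpoint battery run once on the deterministic fixture."""
    return run_all(fixture_cohort, GuardrailConfig(), default_catalog())
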