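import pytest

from metalrisk import builtin_exposure_profiles, builtin_references, bundled_table


@pytest.fixture(scope="session")
def water():
    return bundled_table("water")


@pytest.fixture(scope="session")
def sediment():
    return bundled_table("sediment")


@pytest.fixture(scope="session")
def refs():
    return builtin_references()


@pytest.fixture(scope="session")
def profiles():
    return builtin_exposure_profiles()
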