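import pytest

from mnmkit import CohortSpec, default_vocabulary, generate, load_all_builtin, load_builtin


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def who():
    return load_builtin("who_2011")


@pytest.fixture(scope="session")
def all_sets():
    """The seven near-miss criteria sets (PLTC screen excluded)."""
    return load_all_builtin()


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort, shared across tests (read-only)."""
    return generate(CohortSpec(seed=2024))
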