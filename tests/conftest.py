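import pytest
from hypothesis import settings

from eponymsearch.eponym_io import (
    RootEponym,
    bundled_gi_eponyms_path,
    read_eponym_csv,
    standardize_all,
)


settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gi_raw_path():
    return bundled_gi_eponyms_path()


@pytest.fixture(scope="session")
def gi_roots(gi_raw_path):
    """The standardized 27-root gastrointestinal eponym list."""
    return standardize_all(read_eponym_csv(gi_raw_path))


@pytest.fixture
def zenker():
    return RootEponym(names=("Zenker",), term="Diverticulum", source_row=1)


@pytest.fixture
def mallory_weiss():
    return RootEponym(names=("Mallory", "Weiss"), term="Tear", source_row=2)
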