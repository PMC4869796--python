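import pytest
from hypothesis import HealthCheck, settings

from dxnorm import (
    CanonConfig,
    LexiconRecord,
    compile_dictionary,
    bundled_root_lexicon,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return CanonConfig()


@pytest.fixture(scope="session")
def roots():
    return bundled_root_lexicon()


@pytest.fixture()
def toy_records():
    return [
        LexiconRecord("D000001", "nervous system disease", ("C10",)),
        LexiconRecord("D000002", "chronic airway blockage", ("C08.381",)),
        LexiconRecord("D000002", "blockage of airways", ("C08.381",)),
        LexiconRecord("D000003", "lung cancer", ("C04", "C08")),
        LexiconRecord("D000004", "kidney inflammation", ("C12",)),
    ]


@pytest.fixture()
def toy_dict(toy_records):
    return compile_dictionary(toy_records)
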