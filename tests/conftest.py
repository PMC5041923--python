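import pytest
from hypothesis import HealthCheck, settings

import genemeta as gm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The packaged nine-study rs6983267 prostate-cancer dataset."""
    return gm.load_table1()


@pytest.fixture(scope="session")
def table1_by_id(table1):
    return {s.study_id: s for s in table1}
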