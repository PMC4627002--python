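import numpy as np
import pytest

import ltfbias as lb

HIGH = ">=2085.8 ppt-mo"
REF = "never-exposed"


@pytest.fixture(scope="session")
def table():
    return lb.builtin_table()


@pytest.fixture(scope="session")
def scenarios():
    return {s.name: s for s in lb.builtin_scenarios()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20151015)
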