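import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pytest

from commgem import (
    ToyConfig,
    make_toy_acetogen,
    make_toy_chain_elongator,
    make_toy_propionigen,
    make_toy_triculture,
)


@pytest.fixture(scope="session")
def cfg():
    return ToyConfig()


@pytest.fixture(scope="session")
def acetogen(cfg):
    return make_toy_acetogen(cfg)


@pytest.fixture(scope="session")
def propionigen(cfg):
    return make_toy_propionigen(cfg)


@pytest.fixture(scope="session")
def elongator(cfg):
    return make_toy_chain_elongator(cfg)


@pytest.fixture(scope="session")
def triculture(cfg):
    return make_toy_triculture(cfg, {"aw": 0.5, "an": 0.3, "ck": 0.2})
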