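import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from crisprcensus.annotation import ProfileMap
from crisprcensus.registry import bundled_registry


@pytest.fixture(scope="session")
def reg2025():
    return bundled_registry("2025")


@pytest.fixture(scope="session")
def reg2020():
    return bundled_registry("2020")


@pytest.fixture(scope="session")
def profile_map(reg2025):
    return ProfileMap.from_registry(reg2025)
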