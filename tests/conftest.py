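from datetime import datetime

import pytest

from ivdkit import GeneratorConfig, SourceState, make_toy_away_along

EPOCH = datetime(2024, 3, 20, 9, 0, 0)


@pytest.fixture(scope="session")
def source():
    return SourceState(rakr=38.3, ref_time=EPOCH)


@pytest.fixture(scope="session")
def line_source():
    return SourceState(rakr=38.3, ref_time=EPOCH, active_length=3.5)


@pytest.fixture(scope="session")
def inverse_square_table(source):
    """Toy table whose field is exactly 1.109 / r^2 (point source, no
    attenuation)."""
    return make_toy_away_along(source=source, mu=0.0)


@pytest.fixture(scope="session")
def toy_table(line_source):
    """Toy table with a line-source geometry factor and mild attenuation."""
    return make_toy_away_along(source=line_source, mu=0.01)


@pytest.fixture
def quiet_cfg():
    return GeneratorConfig(seed=0, noise_model="none")
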