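import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from sscquant.cytometry import EventTable, ExposureCondition
from sscquant.synthetic import SyntheticConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def upright_60nm():
    return ExposureCondition(core_diameter=60.0, configuration="upright", media_height=6.0)


@pytest.fixture
def small_table():
    events = pd.DataFrame({"FSC-A": [100.0, 200.0, 300.0], "SSC-A": [1.0, 2.0, 3.0]})
    return EventTable(sample_id="toy", events=events)


@pytest.fixture(scope="session")
def zero_noise_study():
    """A fully deterministic study: every noise source off, small event count."""
    cfg = SyntheticConfig(seed=7, events_per_sample=200).zero_noise()
    return generate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """A default-noise study at reduced event count for speed."""
    cfg = SyntheticConfig(seed=11, events_per_sample=1500)
    return generate_study(cfg)
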