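import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pm25elements.core import SiteSummary
from pm25elements.synth import SynthConfig, make_source_profiles, simulate_dataset, table1_fixture

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_profiles():
    return make_source_profiles(3, seed=1)


@pytest.fixture(scope="session")
def published_summary():
    """Site summary built from the campaign's printed statistics."""
    return SiteSummary.from_site_statistics()


@pytest.fixture(scope="session")
def table1fix():
    return table1_fixture(seed=0)


@pytest.fixture(scope="session")
def mixture_200(preset_profiles):
    """k=3 mixture, n=200, 10% multiplicative noise, fixed seed."""
    cfg = SynthConfig(n_samples={"S1": 200}, cv=0.10, seed=7)
    return simulate_dataset(preset_profiles, cfg)


@pytest.fixture(scope="session")
def noise_free_60(preset_profiles):
    cfg = SynthConfig(n_samples={"S1": 60}, cv=0.0, seed=2)
    return simulate_dataset(preset_profiles, cfg)
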