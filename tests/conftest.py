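import numpy as np
import pytest

from pulmoflow import phantom


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def default_study(default_spec):
    """Noiseless default phantom study (shared; treat as read-only)."""
    return phantom.generate_flow_study(default_spec)


@pytest.fixture(scope="session")
def default_geometry(default_study):
    return default_study.meta["geometry"]


@pytest.fixture(scope="session")
def printed_cohort():
    return phantom.load_printed_cohort()


@pytest.fixture(scope="session")
def p1_spec():
    """Phantom parameterised by the first cohort row (T, SV, RPA split)."""
    return phantom.PhantomSpec(period=0.95, stroke_volume_ml=95.0, rpa_fraction=0.62)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
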