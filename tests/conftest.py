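import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def table1():
    """Reference parameter set (half-life-consistent k2 = 0.08 1/h)."""
    from lucikit import ReporterParams

    return ReporterParams()


@pytest.fixture
def half_hour_grid():
    """72 h at 30-min sampling: 145 points."""
    return np.arange(145) * 0.5
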