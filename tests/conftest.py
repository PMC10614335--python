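import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_library():
    """Three targeting guides over two genes plus one NT control."""
    from dualscreen.library_design import GuideRecord

    return [
        GuideRecord("GA_sg1", "GA", "ACGTACGTACGTACGTACGT"),
        GuideRecord("GA_sg2", "GA", "TTTTACGTACGTACGTACGG"),
        GuideRecord("GB_sg1", "GB", "CCCCACGTACGTACGTACGA"),
        GuideRecord(
            "NTC_sg1",
            "negative_control",
            "GACGACTAGTTAGGCGTGTA",
            is_negative_control=True,
        ),
    ]
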