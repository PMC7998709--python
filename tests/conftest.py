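import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exp_curve():
    """The corrected idealisation of a perfect-doubling curve: F(c) = 2^c.

    Built directly in corrected form (zero baseline mean and sd) so the
    exponential values are exact at every cycle.
    """
    from fluorct import AmplificationCurve

    f = 2.0 ** np.arange(1, 41)
    return AmplificationCurve(
        "S1", "G1", f, baseline_corrected=True, baseline_window=(3, 15), baseline_sd=0.0
    )
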