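import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wearmotion import BodySite, ImuSample, Stream

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def nine_site_stream(rng) -> Stream:
    """A small 9-site, 10-tick stream with varied values and labels."""
    from wearmotion import ActivityLabel

    samples = []
    for k in range(10):
        t = 0.2 * k
        for site in BodySite:
            samples.append(
                ImuSample(
                    site=site,
                    t=t,
                    a=tuple(rng.uniform(-200, 200, size=3)),
                    w=tuple(rng.uniform(-1, 1, size=3)),
                    label=ActivityLabel.STAND,
                )
            )
    return Stream.from_samples(samples)
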