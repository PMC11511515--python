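import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinescore as ks

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 exercise classes x 4 repetitions, 12 s executions with background."""
    return ks.generate_dataset(
        n_classes=3, n_per_class=4, background_fraction=0.25, seed=11, duration=12.0
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    return ks.train(tiny_dataset, ks.PipelineConfig())


@pytest.fixture
def random_sequence():
    """A short skeleton sequence with arbitrary (non-degenerate) geometry."""
    rng = np.random.default_rng(7)
    T = 40
    times = np.arange(T) / 30.0
    xyz = rng.uniform(0.0, 1.0, (T, 20, 3))
    valid = np.ones((T, 20), dtype=bool)
    return ks.SkeletonSequence(times, xyz, valid, 30.0)
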