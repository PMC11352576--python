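import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fretlife import TrackDataset, TrackObservation


def make_dataset(frame_counts, censored, delta_t=1.0, nmin=1):
    obs = [
        TrackObservation(int(n), bool(c), f"t{i}")
        for i, (n, c) in enumerate(zip(frame_counts, censored))
    ]
    return TrackDataset(delta_t=delta_t, min_frame_count=nmin, observations=obs)


def random_dataset(rng, n_max=50, delta_t=1.0, nmin=1, require_uncensored=True):
    """A random small dataset with at least one vanishing track."""
    n = rng.integers(2, n_max + 1)
    counts = rng.geometric(0.25, size=n) + (nmin - 1)
    censored = rng.random(n) < 0.3
    if require_uncensored and censored.all():
        censored[0] = False
    return make_dataset(counts, censored, delta_t=delta_t, nmin=nmin)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
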