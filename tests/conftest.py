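import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hippomvpa import make_blob_mask
from hippomvpa.glm import BetaSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _toy_betas(mask, n_per_class, amplitude, noise, seed, labels=None):
    """Trial × voxel betas with two embedded class patterns plus noise."""
    rng = np.random.default_rng(seed)
    coords = mask.coords()
    nv = len(coords)
    pa, pb = rng.standard_normal(nv), rng.standard_normal(nv)
    if labels is None:
        labels = rng.permutation(np.repeat(["A", "B"], n_per_class))
    X = (
        np.where((np.asarray(labels) == "A")[:, None], pa, pb) * amplitude
        + rng.standard_normal((len(labels), nv)) * noise
    )
    return BetaSeries(X, np.arange(len(labels)), coords), np.asarray(labels)


@pytest.fixture
def toy_betas():
    return _toy_betas


@pytest.fixture
def small_mask():
    return make_blob_mask((10, 10, 8), 12, seed=3)
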