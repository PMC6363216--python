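import numpy as np
import pytest

from equiposture.landmark_io import ShapeSample, ssl_scheme
from equiposture.synthetic import ProfileParams, generate_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def profile():
    """One deterministic 30-point dorsal outline."""
    return generate_profile(ProfileParams())


@pytest.fixture
def profile_sample(rng):
    """Small sample of jittered dorsal outlines under the SSL scheme."""

    def make(n=8, noise=0.5, scheme=None, seed=None):
        gen = np.random.default_rng(seed) if seed is not None else rng
        base = generate_profile(ProfileParams())
        coords = base[None] + gen.normal(0.0, noise, (n, *base.shape))
        from equiposture.landmark_io import LandmarkConfiguration

        configs = [
            LandmarkConfiguration(c, horse_id=f"H{i}", photo_id=f"P{i}")
            for i, c in enumerate(coords)
        ]
        return ShapeSample(configs, scheme or ssl_scheme())

    return make
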