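import numpy as np
import pytest

from morphokin.core import AgeCategory, LandmarkConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(20_0901)


def random_config(rng, specimen_id="s1", population="PopA", age=AgeCategory.ADULT, k=44):
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        population=population,
        age_category=age,
        coords=rng.normal(scale=10.0, size=(k, 3)),
    )


@pytest.fixture
def make_config(rng):
    def _make(**kwargs):
        return random_config(rng, **kwargs)

    return _make


def random_similarity(rng):
    """Random rotation, translation and positive scale."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    scale = float(rng.uniform(0.2, 5.0))
    shift = rng.uniform(-50, 50, size=3)
    return q, scale, shift


def apply_similarity(coords, q, scale, shift):
    return coords @ q * scale + shift
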