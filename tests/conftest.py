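import numpy as np
import pytest

from lvradiomics.synthdata import CohortSpec, generate_cohort


def random_level_image(rng, size=8, ng=4):
    """Small random quantized image + random (but non-trivial) mask."""
    levels = rng.integers(1, ng + 1, size=(size, size))
    mask = rng.random((size, size)) < 0.8
    if mask.sum() < 4:
        mask[:2, :2] = True
    return levels, mask


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small calibrated cohort reused across integration-level tests."""
    spec = CohortSpec.calibrated(n_htn=12, n_nc=12, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
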