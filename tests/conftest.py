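import numpy as np
import pytest
from hypothesis import settings

from odseg import PhantomSpec, detect_od, generate, preprocess

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_phantom():
    """One default clean phantom: (image, truth, spec)."""
    spec = PhantomSpec(rng_seed=123)
    img, truth = generate(spec)
    return img, truth, spec


@pytest.fixture(scope="session")
def clean_detection(clean_phantom):
    """Detection + preprocessing on the shared clean phantom (expensive)."""
    img, truth, spec = clean_phantom
    det = detect_od(img)
    pre = preprocess(img)
    return det, pre


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
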