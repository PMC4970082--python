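import numpy as np
import pytest
from hypothesis import settings

from ahnet.classifier import train_classifier
from ahnet.synthetic import ClassSpec, PiecewiseSpec, gen_classes

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def piecewise_spec():
    """Known in-family ground truth: cubic / quadratic / cubic pieces on
    [0, 3] with true breakpoints at 1 and 2."""
    return PiecewiseSpec(
        bounds=(0.0, 1.0, 2.0, 3.0),
        coefficients=((1.0, -1.5, 0.5, 0.2), (-0.5, 2.0, -1.0), (0.3, -2.0, 4.0, 1.0)),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark: 18 ordered Gaussian classes,
    separation/noise = 6, 200 samples/class, plus an independent test
    draw and the trained classifier."""
    spec = ClassSpec(seed=0)
    train = gen_classes(spec)
    test = gen_classes(spec, noise_seed=1)
    model = train_classifier(train.features, train.labels)
    return spec, train, test, model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
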