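import numpy as np
import pytest

import eegspect as es


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2 subjects, 14 s: enough for fast pipeline-level checks."""
    return es.generate_cohort(es.separable_spec(subjects_per_class=2, duration=14.0, seed=11))


@pytest.fixture(scope="session")
def tiny_images(tiny_cohort):
    return es.images_from_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_features(tiny_images):
    return es.features_from_images(tiny_images)
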