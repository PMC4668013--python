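import numpy as np
import pytest

from pausecode import generate_template_train, segment_isis


@pytest.fixture(scope="session")
def template_train():
    """One 60 s template PN train at default study conditions."""
    return generate_template_train(duration_ms=60_000.0, seed=7)


@pytest.fixture(scope="session")
def template_segmentation(template_train):
    return segment_isis(template_train)


@pytest.fixture(scope="session")
def small_population():
    """A 50-unit, 3 s PN population (fast fixture for synchrony tests)."""
    rng = np.random.default_rng(11)
    return [
        generate_template_train(duration_ms=3000.0, seed=rng, unit_id=k)
        for k in range(50)
    ]
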