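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


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def identity_labelmap():
    """Factory: label map with identity affine from {label: [indices]} specs."""
    from shuntvalve import LabelMap

    def build(placements, shape=(12, 12, 12)):
        labels = np.zeros(shape, dtype=np.int16)
        for label, indices in placements.items():
            for idx in indices:
                labels[tuple(idx)] = label
        return LabelMap(labels=labels, affine=np.eye(4))

    return build
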