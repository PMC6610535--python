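import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_records():
    """Four patients, one per dose group, spanning all risk levels."""
    from psadose.io import PatientRecord

    return [
        PatientRecord("A", 8.0, 6, "T2a", 45.0, 24.0, False, 24.0),
        PatientRecord("B", 15.0, 7, "T2b", 60.0, 30.0, True, 12.0),
        PatientRecord("C", 25.0, 8, "T3", 70.0, 36.0, False, 36.0),
        PatientRecord("D", 5.0, 6, "T1c", 74.0, 18.0, True, 6.0),
    ]
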