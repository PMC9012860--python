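import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sessa import cohort_from_days


@pytest.fixture
def tiny_cohort():
    """Three patients: a regular refiller, a single-fill patient, a pair."""
    return cohort_from_days(
        [
            ("A", 0, 30), ("A", 30, 60), ("A", 90, 30),
            ("B", 10, 30),
            ("C", 0, 30), ("C", 60, 60),
        ],
        window_days=200,
    )
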