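"""Shared fixtures: synthetic segments and a session-scoped default cohort.

The 200-shock cohort and its feature extraction are expensive, so they are
computed once per session and shared by the integration and acceptance
tests; unit tests build their own tiny inputs.
"""

import numpy as np
import pytest

from vfmdi.pipeline import CohortFeatures
from vfmdi.synthetic import CohortSpec, generate_cohort
from vfmdi.types import Channel, SignalSegment

COHORT_SPEC = CohortSpec(n_patients=100, n_shocks=200, seed=7)


def sine_segment(freq=5.0, rate=250.0, duration=9.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return SignalSegment(amplitude * np.sin(2 * np.pi * freq * t + phase), rate,
                         Channel.ECG, segment_id=f"sine{freq}")



@pytest.fixture(scope="session")
def default_cohort():
    """200-shock cohort at the default (separable) study conditions."""
    return generate_cohort(COHORT_SPEC)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    records, _ = default_cohort
    return records, CohortFeatures.from_records(records)
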