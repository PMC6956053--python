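import numpy as np
import pytest

from microcolony.synthdata import (CVScenario, EISScenario, ImagingScenario,
                                   generate_cv_session, generate_eis_session,
                                   generate_image_stack)

EVENT_S = 6 * 3600.0
SESSION_S = 30 * 3600.0


@pytest.fixture(scope="session")
def colonized_cv():
    """Canonical colonization CV session (seed 0) with its ground truth."""
    return generate_cv_session(
        CVScenario(colonization_time_s=EVENT_S, seed=0), SESSION_S)


@pytest.fixture(scope="session")
def control_cv():
    return generate_cv_session(CVScenario(seed=0), SESSION_S)


@pytest.fixture(scope="session")
def colonized_eis():
    return generate_eis_session(
        EISScenario(colonization_time_s=EVENT_S, seed=0), SESSION_S)


@pytest.fixture(scope="session")
def small_stack():
    """Shortened segment stack, cheap enough for per-test reuse."""
    scenario = ImagingScenario(segment_length_px=600, seed=0)
    return generate_image_stack(scenario, 14)
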