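import numpy as np
import pytest

from lirsim.hemodynamic_model import (
    PHASE1_RANGES,
    PatientParams,
    baseline_state,
    sample_patient,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_patient():
    """The reference 75-kg patient used for calibration anchors."""
    return PatientParams(
        weight=75.0, height=67.0, hr_base=70.0, sbp_base=120.0, dbp_base=75.0,
        lvedv_base=140.0, lvesv_base=50.0, blood_volume_base=75.0 * 70.0,
    )


@pytest.fixture
def default_baseline(default_patient):
    return baseline_state(default_patient)


@pytest.fixture
def phase1_patient(rng):
    return sample_patient(PHASE1_RANGES, rng)
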