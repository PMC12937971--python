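import numpy as np
import pytest

from corneafluor.agreement import load_clinical_pairs
from corneafluor.qc import QcConfig
from corneafluor.simulate import (
    CohortConfig,
    RawRecording,
    RecordingConfig,
    SubjectProfile,
)


@pytest.fixture(scope="session")
def clinical():
    """Bundled 20-pair serum vs device comparison dataset."""
    pairs, table = load_clinical_pairs()
    return pairs, table


@pytest.fixture
def default_qc():
    return QcConfig()


@pytest.fixture
def subject():
    return SubjectProfile(
        subject_id="S0000",
        true_age_conc=4.0,
        bmi=24.0,
        diet_score=0.5,
        pigment_class="brown",
        skin_tone="B",
    )


@pytest.fixture
def quiet_recording_config():
    """Noise-free, drift-free, interference-free recording settings."""
    return RecordingConfig(
        noise_sd=0.0,
        drift_amplitude=0.0,
        eyelid_noise_sd=0.0,
        interference_rate=0.0,
        seed=0,
    )


def make_recording(corneal, eyelid, subject_id="S0000", repeat_index=0):
    corneal = np.asarray(corneal, dtype=float)
    eyelid = np.asarray(eyelid, dtype=float)
    return RawRecording(
        subject_id=subject_id,
        repeat_index=repeat_index,
        corneal=corneal,
        eyelid=eyelid,
        truth_interference_mask=np.zeros(len(corneal), dtype=bool),
    )


@pytest.fixture
def small_cohort_config():
    return CohortConfig(n_subjects=30, seed=7)
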