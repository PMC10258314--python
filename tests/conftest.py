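import numpy as np
import pandas as pd
import pytest

from oligogrowth import CohortConfig, compute_cohort_growth_rates, generate_cohort


@pytest.fixture(scope="session")
def synthetic_default():
    """One default synthetic cohort (seed 1) shared across tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_default(synthetic_default):
    return synthetic_default.to_cohort()


@pytest.fixture(scope="session")
def fits_default(cohort_default):
    return compute_cohort_growth_rates(cohort_default)


@pytest.fixture()
def tiny_cohort_frames():
    """Minimal well-formed 3-patient cohort: one measured, one de-novo, one with TP+1."""
    lesions = pd.DataFrame(
        [
            {"patient_id": "A", "timepoint": "TP-1", "lesion_id": "L0",
             "volume_cc": 2.0, "site": "lung"},
            {"patient_id": "A", "timepoint": "TP0", "lesion_id": "L0",
             "volume_cc": 10.0, "site": "lung"},
            {"patient_id": "A", "timepoint": "TP0", "lesion_id": "L1",
             "volume_cc": 18.4, "site": "liver"},
            {"patient_id": "B", "timepoint": "TP0", "lesion_id": "L0",
             "volume_cc": 28.4, "site": "brain"},
            {"patient_id": "C", "timepoint": "TP-1", "lesion_id": "L0",
             "volume_cc": 5.0, "site": "bone"},
            {"patient_id": "C", "timepoint": "TP0", "lesion_id": "L0",
             "volume_cc": 5.0, "site": "bone"},
            {"patient_id": "C", "timepoint": "TP+1", "lesion_id": "L0",
             "volume_cc": 2.5, "site": "bone"},
        ]
    )
    patients = pd.DataFrame(
        [
            {"patient_id": "A", "de_novo": 0, "tp_minus1_offset_days": -90.0,
             "primary_site": "cutaneous", "brain_met": 0, "liver_met": 1,
             "bone_met": 0, "lung_met": 1, "os_days": 400.0, "os_event": 1,
             "pfs_days": 200.0, "pfs_event": 1, "pfs2_days": 300.0,
             "pfs2_event": 1, "best_response": "SD"},
            {"patient_id": "B", "de_novo": 1, "tp_minus1_offset_days": np.nan,
             "primary_site": "mucosal", "brain_met": 1, "liver_met": 0,
             "bone_met": 0, "lung_met": 0, "os_days": 900.0, "os_event": 0,
             "pfs_days": 500.0, "pfs_event": 1, "pfs2_days": 700.0,
             "pfs2_event": 1, "best_response": "PD"},
            {"patient_id": "C", "de_novo": 0, "tp_minus1_offset_days": -60.0,
             "primary_site": "ocular", "brain_met": 0, "liver_met": 0,
             "bone_met": 1, "lung_met": 0, "os_days": 1200.0, "os_event": 0,
             "pfs_days": 1200.0, "pfs_event": 0, "pfs2_days": 1200.0,
             "pfs2_event": 0, "best_response": "PR"},
        ]
    )
    return lesions, patients


@pytest.fixture()
def tiny_cohort_files(tmp_path, tiny_cohort_frames):
    lesions, patients = tiny_cohort_frames
    lp = tmp_path / "lesions.csv"
    pp = tmp_path / "patients.csv"
    lesions.to_csv(lp, index=False)
    patients.to_csv(pp, index=False)
    return lp, pp
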