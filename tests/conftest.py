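import numpy as np
import pandas as pd
import pytest

from hdpsmatch.simulate import ClaimsDataset, SimulationConfig

EMPTY_EVENTS = pd.DataFrame(
    columns=["patient_id", "dimension_id", "code", "days_before_entry"])
EMPTY_DISP = pd.DataFrame(
    columns=["patient_id", "product", "daily_dose", "days_relative_to_entry"])
EMPTY_DIAG = pd.DataFrame(columns=["patient_id", "code", "days_relative_to_entry"])


def toy_patient(patient_id=1, age=60.0, entry_year=2005, **extra):
    row = {"patient_id": patient_id, "age": age, "entry_year": entry_year}
    row.update(extra)
    return row


def make_dataset(patients_rows, disp_rows=None, diag_rows=None, events_rows=None):
    """Assemble a raw-mode ClaimsDataset from row dicts."""
    return ClaimsDataset(
        patients=pd.DataFrame(patients_rows),
        events=pd.DataFrame(events_rows) if events_rows else EMPTY_EVENTS.copy(),
        dispensations=(pd.DataFrame(disp_rows) if disp_rows else EMPTY_DISP.copy()),
        diagnoses=pd.DataFrame(diag_rows) if diag_rows else EMPTY_DIAG.copy(),
    )


def index_statin(patient_id, product="pravastatin", dose=20.0, day=0):
    return {"patient_id": patient_id, "product": product, "daily_dose": dose,
            "days_relative_to_entry": day}


@pytest.fixture(scope="session")
def small_config():
    """A small default-structure simulation: all confounding at defaults."""
    return SimulationConfig(
        n_patients=4000, seed=17,
        n_codes_per_dimension={d: 8 for d in range(1, 7)})


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from hdpsmatch.simulate import generate_population
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    from hdpsmatch.cohort import apply_inclusion_exclusion
    cohort, _ = apply_inclusion_exclusion(small_dataset)
    return cohort
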