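import numpy as np
import pandas as pd
import pytest

from ctsurveil.io import EHRBundle, ReportRecord


@pytest.fixture(scope="session")
def small_study():
    """A small but fully populated synthetic study shared across tests."""
    from ctsurveil.synthetic import GeneratorConfig, simulate_study

    return simulate_study(GeneratorConfig(n_patients=80, n_controls=20, seed=42))


@pytest.fixture()
def toy_bundle():
    """Two patients, three scans, hand-sized tables for exact assertions."""
    ct_events = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2"],
        "date": ["2015-03-01", "2016-01-15", "2015-06-01"],
        "report_id": ["R1", "R2", "R3"],
    })
    diagnoses = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2"],
        "date": ["2015-12-01", "2015-05-01", "2015-05-30"],
        "icd_code": ["R05", "J18.9", "R07.9"],
    })
    orders = pd.DataFrame({
        "report_id": ["R1", "R2", "R3"],
        "provider_specialty": ["Medical Oncology", "Emergency Medicine", "Basket Weaving"],
    })
    demographics = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "sex": ["female", "male"],
        "race_ethnicity": ["white", "asian"],
        "stage": ["I", "IV"],
        "histology": ["adenocarcinoma", "squamous_cell"],
    })
    outcomes = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "time_origin_date": ["2015-01-01", "2015-01-01"],
        "last_followup_date": ["2020-01-01", "2017-06-01"],
        "death_indicator": [0, 1],
    })
    reports = [
        ReportRecord("R1", "P1", "2015-03-01", "INDICATION: surveillance. FINDINGS: clear."),
        ReportRecord("R2", "P1", "2016-01-15", "INDICATION: cough. FINDINGS: clear."),
        ReportRecord("R3", "P2", "2015-06-01", "INDICATION: follow-up. FINDINGS: clear."),
    ]
    bundle = EHRBundle(ct_events=ct_events, diagnoses=diagnoses, orders=orders,
                       demographics=demographics, outcomes=outcomes)
    return reports, bundle.validate(reports)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
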