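import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from ccval.data_model import TableBundle, empty_table
from ccval.generator import GeneratorConfig, generate_with_truth
from ccval.pipeline import PipelineConfig, run_pipeline

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


def _d(iso: str) -> pd.Timestamp:
    return pd.Timestamp(iso)


@pytest.fixture()
def hand_bundle() -> TableBundle:
    """A three-person bundle small enough to reason about by hand.

    Person a: invited, two back-pain diagnoses only (class 1 pattern).
    Person b: invited, opioid pair + sick leave (class 3 pattern).
    Person c: self-selected, below the two-diagnosis threshold.
    """
    diagnoses = pd.DataFrame(
        {
            "person_id": ["a", "a", "b", "b", "c"],
            "code": ["M54.5", "M51.1", "M54.5", "M54.5", "M54.5"],
            "date": [_d("2019-03-01"), _d("2019-06-01"), _d("2019-02-10"),
                     _d("2019-08-01"), _d("2019-05-05")],
        }
    )
    prescriptions = pd.DataFrame(
        {
            "person_id": ["b", "b"],
            "atc_code": ["N02AA01", "N02AB03"],
            "date": [_d("2019-04-01"), _d("2019-05-15")],
        }
    )
    sick_leave = pd.DataFrame(
        {
            "person_id": ["b"],
            "start": [_d("2019-03-01")],
            "end": [_d("2019-03-21")],
            "attributed_code": ["M54.5"],
        }
    )
    invoices = pd.DataFrame(
        {
            "person_id": ["a", "a", "b"],
            "date": [_d("2019-09-01"), _d("2019-10-01"), _d("2019-09-15")],
            "category": ["total_health", "bp_outpatient", "total_health"],
            "amount": [1200.50, 80.00, 3500.00],
            "year": [2019, 2019, 2019],
        }
    )
    enrolment = pd.DataFrame(
        {
            "person_id": ["a", "b", "c"],
            "invitation_date": [_d("2019-09-01"), _d("2019-09-01"), pd.NaT],
            "enrolment_date": [_d("2019-10-01"), _d("2019-11-29"), _d("2019-10-15")],
            "path": ["invited", "invited", "self_selected"],
            "sick_leave_insured": [True, False, True],
        }
    )
    gcps_items = pd.DataFrame(
        {
            "person_id": ["a", "b", "c"],
            "pain_now": [2, 7, 5],
            "pain_avg": [3, 8, 5],
            "pain_worst": [4, 9, 6],
            "interf_daily": [1, 8, 4],
            "interf_social": [0, 7, 3],
            "interf_work": [2, 9, 5],
            "disability_days": [3, 60, 10],
        }
    )
    return TableBundle(
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        sick_leave=sick_leave,
        invoices=invoices,
        enrolment=enrolment,
        gcps_items=gcps_items,
    )


@pytest.fixture(scope="session")
def gen_run():
    """One deterministic generator run shared across tests (n=2000)."""
    config = GeneratorConfig(n_persons=2000, seed=11)
    bundle, manifest, persons = generate_with_truth(config)
    return config, bundle, manifest, persons


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run shared across tests (n=4000)."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(
        generator=GeneratorConfig(n_persons=4000, seed=17), output_dir=out
    )
    result = run_pipeline(config)
    return config, result, out
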