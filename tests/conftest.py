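import numpy as np
import pandas as pd
import pytest

from ckd_labscan.cohort_builder import RECORD_COLUMNS


def make_records(rows):
    """Build a lab-record table from compact row dicts (defaults filled in)."""
    defaults = {
        "patient_id": "p1",
        "sex": "female",
        "birth_year": 1970,
        "test_type": "creatinine",
        "value": "1.0",
        "unit": "",
        "collection_date": "2019-06-01",
        "specialty": "other",
        "setting": "outpatient",
        "region": "SP",
    }
    table = pd.DataFrame([{**defaults, **row} for row in rows], columns=RECORD_COLUMNS)
    table["collection_date"] = pd.to_datetime(table["collection_date"])
    table["record_id"] = np.arange(len(table))
    return table


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
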