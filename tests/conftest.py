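import numpy as np
import pytest
from hypothesis import settings

from fdacbr.curves import RiskSeries
from fdacbr.encoding import default_scheme

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: risk trajectory of the worked single-resident example: ten consecutive
#: half-yearly examinations (indices 11..20) with slowly drifting risk
TABLE_RISKS = (13.6, 13.2, 13.8, 14.5, 15.6, 15.9, 15.4, 15.8, 15.7, 16.2)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def reference_series():
    return RiskSeries("ref", np.arange(11.0, 21.0), np.array(TABLE_RISKS))


@pytest.fixture()
def raw_record():
    """A complete raw exam record covering every default attribute."""
    return {
        "gender": "Male",
        "age": 52.0,
        "exercise_frequency": "Occasionally",
        "dietary_habit": "Equilibrium",
        "smoking": "Never",
        "drinking": "Never",
        "heart_rhythm": "Normal",
        "central_obesity": "No",
        "bmi": 25.0,
        "diabetes": "No",
        "heart_rate": 80.0,
        "blood_urea": 5.0,
        "total_cholesterol": 4.6,
        "triglyceride": 1.2,
        "ldl_cholesterol": 3.0,
        "hdl_cholesterol": 1.4,
    }
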