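import pandas as pd
import pytest

from fuzzyicu import THERAPY_LABELS, build_domain


@pytest.fixture(scope="session")
def therapy_days_domain():
    """The published worked example: total days of antimicrobial therapy.

    Trimmed range [0, 22] days, trimmed median 11, overlap half-width 1.8.
    """
    return build_domain(0.0, 22.0, 11.0, 1.8, labels=THERAPY_LABELS, parameter_id="overall_days")


@pytest.fixture()
def two_drug_admins():
    """Drug A on days 1-2, drug B on days 2-3, one patient."""
    return pd.DataFrame(
        {
            "patient_id": ["p1"] * 4,
            "drug": ["A", "A", "B", "B"],
            "date": ["2020-01-01", "2020-01-02", "2020-01-02", "2020-01-03"],
        }
    )
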