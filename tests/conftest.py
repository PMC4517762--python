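import pytest

from psascreen.cohort import BiopsyGS, Outcome, PatientRecord
from psascreen.synthetic import default_spec, generate_cohort


def make_record(
    age=60,
    psa=4.0,
    fpsa=15.0,
    malignant=False,
    gs=None,
    pid="p",
    **kwargs,
):
    return PatientRecord(
        patient_id=pid,
        age=age,
        psa=psa,
        fpsa_pct=fpsa,
        outcome=Outcome.MALIGNANT if malignant else Outcome.BENIGN,
        biopsy_gs=gs,
        **kwargs,
    )


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default calibrated cohort (published group sizes, seed 17)."""
    return generate_cohort(default_spec(seed=17))


@pytest.fixture
def four_record_cohort():
    """Malignant flagged / malignant missed / benign flagged / benign clean
    under the revised rule (age 60-69: low cut-off 2.25, threshold 21%)."""
    return [
        make_record(age=65, psa=6.0, fpsa=15.0, malignant=True, gs=BiopsyGS.GS7_34, pid="m-flag"),
        make_record(age=65, psa=1.0, fpsa=15.0, malignant=True, gs=BiopsyGS.GS6, pid="m-miss"),
        make_record(age=65, psa=6.0, fpsa=15.0, malignant=False, pid="b-flag"),
        make_record(age=65, psa=1.0, fpsa=15.0, malignant=False, pid="b-clean"),
    ]
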