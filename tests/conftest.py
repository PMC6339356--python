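import datetime

import pytest
from hypothesis import settings

from katascore.records import LabPanel, PatientRecord

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

RT_START = datetime.date(2010, 1, 1)
LAB_DATE = datetime.date(2009, 12, 20)

NORMAL_LABS = dict(
    crp=0.1, ldh=180.0, albumin=4.2, platelets=250_000.0, calcium=9.2,
    bilirubin=0.6,
)


def make_record(
    patient_id="P1",
    survival_months=6.0,
    event="died",
    sex="male",
    age_years=60,
    kps=70,
    ecog=1,
    primary_site="lung",
    visceral="nodular",
    prior_chemo=False,
    multiple_bone_mets=True,
    labs=None,
    rt_start=RT_START,
    **lab_overrides,
):
    if labs is None:
        values = dict(NORMAL_LABS)
        values.update(lab_overrides)
        labs = LabPanel(panel_date=LAB_DATE, **values)
    return PatientRecord(
        patient_id=patient_id,
        survival_months=survival_months,
        event=event,
        sex=sex,
        age_years=age_years,
        kps=kps,
        ecog=ecog,
        primary_site=primary_site,
        visceral=visceral,
        prior_chemo=prior_chemo,
        multiple_bone_mets=multiple_bone_mets,
        labs=labs,
        rt_start=rt_start,
    )


@pytest.fixture
def favorable_record():
    """All-favorable patient: slow primary, no visceral spread, normal labs,
    ECOG 0, chemo-naive, solitary metastasis -> total score 0."""
    return make_record(
        primary_site="breast", visceral="none", ecog=0,
        prior_chemo=False, multiple_bone_mets=False,
    )


@pytest.fixture
def adverse_record():
    """All-adverse patient -> total score 10."""
    return make_record(
        primary_site="lung", visceral="disseminated", ecog=3,
        prior_chemo=True, multiple_bone_mets=True,
        platelets=60_000.0, crp=5.0,
    )
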