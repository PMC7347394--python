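import numpy as np
import pandas as pd
import pytest

from neorisk.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_10k():
    """Default-configuration cohort, shared across marginal-frequency tests."""
    return generate_cohort(CohortConfig(n=10000, seed=42))


@pytest.fixture(scope="session")
def cohort_small():
    return generate_cohort(CohortConfig(n=400, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def minimal_patient(**overrides):
    """One fully-specified patient record (as a dict) for scoring tests."""
    base = dict(
        id="P1", maternal_steroids="full", chorioamnionitis=0,
        maternal_hypertension=0, multiple_pregnancy=0, sex="female",
        gestational_age=29.0, birth_weight=1100, low_weight_p10=0, inborn=1,
        level_of_care=3, cesarean=1, resuscitation="nil", apgar1=8, apgar5=9,
        admission_temp=36.0, crib1=1, postnatal_steroids=0,
        rds=0, pneumothorax=0, pda=0, nec=0, gi_perforation=0,
        early_sepsis=0, late_sepsis=0, ivh=0, pvl=0, rop=0, bpd=0,
        advanced_resuscitation=0, severe_rds=0, severe_pda=0, severe_nec=0,
        severe_infection=0, severe_rop=0, severe_ivh=0, severe_pvl=0,
        severe_bpd=0, severe_pneumothorax=0, severe_anemia=0,
    )
    base.update(overrides)
    return base
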