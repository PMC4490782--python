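import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import claimsignal as cs
from claimsignal.claims_model import ClaimsBundle, default_code_map, normalize_enrollment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_bundle(
    pharmacy=None,
    medical=None,
    enrollment=None,
    death=None,
    subjects=None,
):
    """Hand-built tiny bundle: rows are tuples matching the table schemas."""
    ph = pd.DataFrame(
        pharmacy or [], columns=["subject_id", "dispense_day", "days_supply", "drug_class"]
    )
    md = pd.DataFrame(
        medical or [], columns=["subject_id", "service_day", "primary_dx", "setting"]
    )
    en = pd.DataFrame(
        enrollment or [], columns=["subject_id", "start_month", "end_month"]
    )
    dt = pd.DataFrame(death or [], columns=["subject_id", "death_day"])
    ids = sorted(
        set(ph["subject_id"]) | set(md["subject_id"]) | set(en["subject_id"]) | set(dt["subject_id"])
    )
    if subjects is None:
        subjects = [(i, 1930, "F") for i in ids]
    sub = pd.DataFrame(subjects, columns=["subject_id", "birth_year", "sex"])
    en = en.merge(sub, on="subject_id", how="left")
    return ClaimsBundle(
        pharmacy=ph,
        medical=md,
        enrollment=normalize_enrollment(en) if len(en) else en,
        death=dt,
        subjects=sub,
        code_map=default_code_map(),
    )


@pytest.fixture(scope="session")
def config():
    return cs.StudyConfig()


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated bundle shared by structural tests."""
    spec = cs.preset("gi_effect", n_subjects=800, seed=11)
    bundle, truth = cs.simulate_bundle(spec)
    return spec, bundle, truth
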