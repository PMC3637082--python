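from datetime import date, datetime

import pytest

from matcare.defaults import (
    default_catalog,
    default_registry,
    default_ruleset,
    default_schedule,
    default_template,
)
from matcare.model import ANCVisit, Observation
from matcare.records import new_record

AS_OF = date(2024, 7, 1)


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


def make_record(patient_id="P1", lmp=date(2024, 1, 1)):
    return new_record(patient_id, "Ama", 24, 2, 1, lmp,
                      now=datetime(2024, 2, 1, 9, 0), today=AS_OF)


def record_with_observations(values: dict, visit_date=date(2024, 3, 1)):
    """Record with one visit holding one observation per (code, value)."""
    record = make_record()
    vocab = default_ruleset().vocabulary
    visit = ANCVisit(visit_number=1, date=visit_date)
    for i, (code, value) in enumerate(values.items()):
        unit = vocab[code].unit if code in vocab else ""
        visit.observations.append(Observation(
            code=code, value=value, unit=unit,
            observed_at=datetime(2024, 3, 1, 9, i)))
    record.open_pregnancy().visits.append(visit)
    return record, visit


@pytest.fixture
def small_cohort():
    from matcare.synthetic import SyntheticSpec, generate_cohort
    return generate_cohort(SyntheticSpec(n_patients=25, seed=11))
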