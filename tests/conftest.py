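import pytest
from hypothesis import settings

from dldpheno.model import CodeEvent, CodeSystem, PatientRecord
from dldpheno.training import LabeledCohort, train_filters

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

LD = "31531"


def ev(code: str, age: int) -> CodeEvent:
    system = CodeSystem.ICD9 if code[0].isdigit() or code[0] in "EV" else CodeSystem.ICD10
    return CodeEvent(code=code, system=system, age_days=age)


def make_record(record_id: str, pairs) -> PatientRecord:
    return PatientRecord(record_id=record_id, events=tuple(ev(c, a) for c, a in pairs))


# One record per category; codes A/B/C/D/E rendered as numeric ICD-9-shaped
# strings. Raw lists R1={A,B,L}, R2={A,C,L}, R3={C,D,L}, R4={D,E,L} so the
# subtracted filters are ({A,B,L},{C},{D},{E}).
A, B, C, D, E = "1001", "1002", "2001", "3001", "4001"


@pytest.fixture
def toy_cohort() -> LabeledCohort:
    records = [
        make_record("r1", [(A, 100), (B, 150), (LD, 200)]),
        make_record("r2", [(A, 100), (C, 300), (LD, 200)]),
        make_record("r3", [(C, 100), (D, 150), (LD, 200)]),
        make_record("r4", [(D, 100), (E, 150), (LD, 200)]),
    ]
    labels = {"r1": 1, "r2": 2, "r3": 3, "r4": 4}
    return LabeledCohort(records=records, labels=labels)


@pytest.fixture
def toy_filters(toy_cohort):
    return train_filters(toy_cohort)
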