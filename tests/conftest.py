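import datetime as dt

import pytest

from pathflow import (
    ClinicalEvent,
    NoiseSettings,
    OutcomeLabel,
    PathwayAllocation,
    SyntheticSpec,
    TreatmentCode,
    TreatmentSequence,
)

A = TreatmentCode.ANTIPLATELET
L = TreatmentCode.LIPID_LOWERING
SC = TreatmentCode.SMOKING_CESSATION
ET = TreatmentCode.EXERCISE_THERAPY
ER = TreatmentCode.ENDOVASCULAR_REVASCULARIZATION
RS = TreatmentCode.REVASCULARIZATION_SURGERY
AMP = OutcomeLabel.AMPUTATION
NON = OutcomeLabel.NON_AMPUTATION


def ev(pid: str, code, day: int) -> ClinicalEvent:
    """Shorthand event on day-offset from 2020-01-01; code may be a
    TreatmentCode or the string 'amputation'."""
    return ClinicalEvent(pid, code, dt.date(2020, 1, 1) + dt.timedelta(days=day))


def seq(pid: str, outcome, *steps) -> TreatmentSequence:
    return TreatmentSequence(person_id=pid, outcome=outcome, steps=tuple(steps))


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    """A 12-patient mixed cohort, default noise."""
    return SyntheticSpec(
        dataset_label="tiny",
        allocations=(
            PathwayAllocation((A, L), AMP, 2),
            PathwayAllocation((ER,), AMP, 1),
            PathwayAllocation((A, L), NON, 4),
            PathwayAllocation((L,), NON, 3),
            PathwayAllocation((SC, ET), NON, 2),
        ),
        seed=11,
    )


@pytest.fixture
def noiseless_spec(tiny_spec) -> SyntheticSpec:
    from dataclasses import replace

    return replace(
        tiny_spec,
        noise=NoiseSettings(p_duplicate_event=0.0, p_post_outcome_event=0.0),
    )
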