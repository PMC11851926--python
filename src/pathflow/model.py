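"""Domain types shared by every pipeline stage.

The vocabulary is fixed: six treatment categories for peripheral artery
disease (antiplatelet therapy, lipid-lowering therapy, smoking cessation,
exercise therapy, endovascular revascularization, revascularization
surgery) plus the distinguished amputation outcome event.  Mapping raw
ICD/CPT/SNOMED codes onto these categories is the caller's responsibility;
this package consumes already-categorized event codes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable


class TreatmentCode(Enum):
    """One of the six recognized treatment categories.

    Enum definition order is the canonical order used to break same-date
    ties during sequence extraction.
    """

    ANTIPLATELET = "antiplatelet"
    LIPID_LOWERING = "lipid_lowering"
    SMOKING_CESSATION = "smoking_cessation"
    EXERCISE_THERAPY = "exercise_therapy"
    ENDOVASCULAR_REVASCULARIZATION = "endovascular_revascularization"
    REVASCULARIZATION_SURGERY = "revascularization_surgery"

    @property
    def label(self) -> str:
        """Human-readable display label, e.g. ``"Lipid lowering"``."""
        return self.value.replace("_", " ").capitalize()

    @property
    def canonical_rank(self) -> int:
        return _TREATMENT_RANK[self]

    def __lt__(self, other: "TreatmentCode") -> bool:  # lexicographic on value
        if not isinstance(other, TreatmentCode):
            return NotImplemented
        return self.value < other.value


_TREATMENT_RANK = {code: i for i, code in enumerate(TreatmentCode)}

#: Distinguished event code marking the amputation outcome.
AMPUTATION_CODE = "amputation"

#: All recognized event-code strings (6 treatments + the outcome).
EVENT_VOCABULARY = frozenset(c.value for c in TreatmentCode) | {AMPUTATION_CODE}


class OutcomeLabel(Enum):
    AMPUTATION = "amputation"
    NON_AMPUTATION = "non_amputation"

    @property
    def label(self) -> str:
        return self.value.replace("_", " ").capitalize()


class Comorbidity(Enum):
    DIABETES = "diabetes"
    HYPERTENSION = "hypertension"
    HEART_FAILURE = "heart_failure"
    CEREBROVASCULAR_DISEASE = "cerebrovascular_disease"
    CORONARY_ARTERY_DISEASE = "coronary_artery_disease"
    HYPERLIPIDEMIA = "hyperlipidemia"


def parse_event_code(token: str) -> "TreatmentCode | str":
    """Parse an event-code token into a TreatmentCode or AMPUTATION_CODE.

    Matching is case-insensitive and tolerant of spaces vs underscores.
    Raises ValueError for anything outside the 7-code vocabulary.
    """
    norm = token.strip().lower().replace(" ", "_").replace("-", "_")
    if norm == AMPUTATION_CODE:
        return AMPUTATION_CODE
    try:
        return TreatmentCode(norm)
    except ValueError:
        raise ValueError(
            f"unrecognized event code {token!r}; expected one of "
            f"{sorted(EVENT_VOCABULARY)}"
        ) from None


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated, categorized event for one patient."""

    person_id: str
    code: "TreatmentCode | str"  # TreatmentCode or AMPUTATION_CODE
    date: _dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.code, TreatmentCode) and self.code != AMPUTATION_CODE:
            raise ValueError(f"invalid event code {self.code!r}")
        if not isinstance(self.date, _dt.date):
            raise TypeError("date must be a datetime.date")

    @property
    def is_outcome(self) -> bool:
        return self.code == AMPUTATION_CODE

    @property
    def code_value(self) -> str:
        return self.code.value if isinstance(self.code, TreatmentCode) else self.code


@dataclass(frozen=True)
class PatientAttributes:
    """Demographics and comorbidity flags for one patient."""

    person_id: str
    age: int
    gender: str
    race: str
    smoker: bool
    comorbidities: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age {self.age} for person {self.person_id!r}")
        bad = [c for c in self.comorbidities if not isinstance(c, Comorbidity)]
        if bad:
            raise ValueError(f"unknown comorbidity flags {bad!r}")


@dataclass(frozen=True)
class TreatmentSequence:
    """A patient's ordered tuple of distinct first-occurrence treatments.

    This is the pipeline's atomic unit: for amputation patients, the
    distinct treatments received strictly before the first amputation, in
    chronological order; for non-amputation patients, over the full record.
    """

    person_id: str
    outcome: OutcomeLabel
    steps: tuple

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("steps must be non-empty (inclusion rule)")
        if len(self.steps) > len(TreatmentCode):
            raise ValueError("more steps than treatment categories")
        if len(set(self.steps)) != len(self.steps):
            raise ValueError(f"repeated treatment in steps {self.steps!r}")
        for s in self.steps:
            if not isinstance(s, TreatmentCode):
                raise TypeError(f"step {s!r} is not a TreatmentCode")


@dataclass(frozen=True)
class CohortSummary:
    dataset_label: str
    n_amputation: int
    n_non_amputation: int

    def __post_init__(self) -> None:
        if self.n_amputation < 0 or self.n_non_amputation < 0:
            raise ValueError("cohort counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_amputation + self.n_non_amputation


def pathway_key(steps: Iterable[TreatmentCode]) -> tuple:
    """Tuple of code values, the lexicographic sort key for a pathway."""
    return tuple(s.value for s in steps)


def format_pathway(steps: Iterable[TreatmentCode], sep: str = " → ") -> str:
    return sep.join(s.label for s in steps)


def round_half_up(value: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero (decimal ROUND_HALF_UP semantics).

    Used for all reported percentage rates and probabilities, so that
    e.g. 2.5% at 0 digits reports as 3, not Python's banker's 2.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = value if isinstance(value, Decimal) else Decimal(repr(value))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """Exact-decimal cohort rate: 100*count/total, half-away-from-zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(Decimal(100 * count) / Decimal(total), ndigits)
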