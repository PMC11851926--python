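"""Seeded synthetic EHR cohort generator.

The generator is specification-driven: a :class:`SyntheticSpec` lists
pathway allocations — (ordered treatment tuple, outcome, patient count)
— and the generator emits an event log and person table such that
running sequence extraction over the output reproduces the allocation
table exactly, regardless of the noise settings.  Noise emulates two
artifacts of real EHR extracts the extraction stage must survive:

* duplicate treatment events — repeat orders of a category the patient
  already received, dated on/after its first occurrence and (for
  amputation patients) strictly before the amputation;
* post-outcome events — for amputation patients, arbitrary treatment
  events after the amputation date (care continues after the outcome);
  for non-amputation patients there is no outcome date, so trailing
  noise is restricted to further duplicates of categories already in
  the record (anything else would, by construction, belong to the
  sequence).

Identical (spec, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from typing import Iterable

from .model import (
    ClinicalEvent,
    Comorbidity,
    OutcomeLabel,
    PatientAttributes,
    TreatmentCode,
)

#: Default comorbidity prevalences: overall stratum proportions implied by
#: the STARR risk-factor counts over the 5581-patient cohort.
DEFAULT_COMORBIDITY_PREVALENCE: dict[Comorbidity, float] = {
    Comorbidity.DIABETES: 0.36,
    Comorbidity.HYPERTENSION: 0.69,
    Comorbidity.HEART_FAILURE: 0.23,
    Comorbidity.CEREBROVASCULAR_DISEASE: 0.32,
    Comorbidity.CORONARY_ARTERY_DISEASE: 0.46,
    Comorbidity.HYPERLIPIDEMIA: 0.90,
}

DEFAULT_SMOKER_PREVALENCE = 0.93
DEFAULT_MALE_PROBABILITY = 0.5
#: Race weights from the STARR marginals, with an other/unknown residual.
DEFAULT_RACE_WEIGHTS: tuple[tuple[str, float], ...] = (
    ("white", 0.60),
    ("black", 0.06),
    ("asian", 0.13),
    ("other", 0.21),
)


@dataclass(frozen=True)
class NoiseSettings:
    """Probabilities are per noise slot; each patient gets
    ``max_extra_events`` independent slots of each noise kind."""

    p_duplicate_event: float = 0.25
    p_post_outcome_event: float = 0.25
    max_extra_events: int = 3

    def validate(self) -> None:
        for name in ("p_duplicate_event", "p_post_outcome_event"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.max_extra_events < 0:
            raise ValueError("max_extra_events must be >= 0")


@dataclass(frozen=True)
class AttributeTemplate:
    """Per-allocation attribute overrides; unset fields fall back to the
    spec-level random defaults.  ``age`` may be a fixed int or an
    inclusive (lo, hi) range."""

    age: "int | tuple[int, int] | None" = None
    gender: str | None = None
    race: str | None = None
    smoker: bool | None = None
    comorbidities: frozenset | None = None


@dataclass(frozen=True)
class PathwayAllocation:
    steps: tuple
    outcome: OutcomeLabel
    n_patients: int
    attributes: AttributeTemplate | None = None

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.steps:
            raise ValueError("allocation with empty steps")
        if len(self.steps) > len(TreatmentCode) or len(set(self.steps)) != len(self.steps):
            raise ValueError(f"invalid pathway {self.steps!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    dataset_label: str
    allocations: tuple
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    confounder_prevalence: dict = field(default_factory=dict)
    smoker_prevalence: float = DEFAULT_SMOKER_PREVALENCE
    date_start: _dt.date = _dt.date(2015, 1, 1)
    mean_gap_days: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "allocations", tuple(self.allocations))

    def validate(self) -> None:
        if not self.allocations:
            raise ValueError("spec has no allocations")
        for alloc in self.allocations:
            alloc.validate()
        self.noise.validate()
        for flag, p in self.confounder_prevalence.items():
            if not isinstance(flag, Comorbidity):
                raise ValueError(f"unknown confounder {flag!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {flag} outside [0, 1]")
        if not 0.0 <= self.smoker_prevalence <= 1.0:
            raise ValueError("smoker_prevalence outside [0, 1]")
        if self.mean_gap_days <= 0:
            raise ValueError("mean_gap_days must be > 0")

    def cohort_sizes(self) -> dict:
        sizes: dict[OutcomeLabel, int] = {}
        for alloc in self.allocations:
            sizes[alloc.outcome] = sizes.get(alloc.outcome, 0) + alloc.n_patients
        return sizes


def _draw_gap(rng: random.Random, mean_gap: float) -> int:
    # >= 1 day so within-patient dates are strictly increasing.
    return 1 + int(rng.expovariate(1.0 / mean_gap))


def _draw_attributes(
    rng: random.Random, spec: SyntheticSpec, person_id: str, template: AttributeTemplate | None
) -> PatientAttributes:
    t = template or AttributeTemplate()
    if t.age is None:
        age = min(95, max(30, round(rng.gauss(69.0, 11.0))))
    elif isinstance(t.age, tuple):
        age = rng.randint(*t.age)
    else:
        age = t.age
    gender = t.gender if t.gender is not None else (
        "male" if rng.random() < DEFAULT_MALE_PROBABILITY else "female"
    )
    if t.race is not None:
        race = t.race
    else:
        u, race = rng.random(), DEFAULT_RACE_WEIGHTS[-1][0]
        acc = 0.0
        for name, w in DEFAULT_RACE_WEIGHTS:
            acc += w
            if u < acc:
                race = name
                break
    smoker = t.smoker if t.smoker is not None else rng.random() < spec.smoker_prevalence
    if t.comorbidities is not None:
        flags = frozenset(t.comorbidities)
    else:
        prev = {**DEFAULT_COMORBIDITY_PREVALENCE, **spec.confounder_prevalence}
        flags = frozenset(c for c in Comorbidity if rng.random() < prev[c])
    return PatientAttributes(
        person_id=person_id, age=age, gender=gender, race=race, smoker=smoker,
        comorbidities=flags,
    )


def _generate_patient_events(
    rng: random.Random, spec: SyntheticSpec, person_id: str, alloc: PathwayAllocation
) -> list[ClinicalEvent]:
    from .model import AMPUTATION_CODE

    noise = spec.noise
    # Base first-occurrence dates, strictly increasing.
    dates: list[_dt.date] = []
    cursor = spec.date_start + _dt.timedelta(days=rng.randint(0, 365))
    for _ in alloc.steps:
        dates.append(cursor)
        cursor += _dt.timedelta(days=_draw_gap(rng, spec.mean_gap_days))
    first_date = dict(zip(alloc.steps, dates))
    events = [
        ClinicalEvent(person_id, code, d) for code, d in zip(alloc.steps, dates)
    ]

    amp_date: _dt.date | None = None
    if alloc.outcome is OutcomeLabel.AMPUTATION:
        amp_date = dates[-1] + _dt.timedelta(days=_draw_gap(rng, spec.mean_gap_days))
        events.append(ClinicalEvent(person_id, AMPUTATION_CODE, amp_date))

    # Duplicate-treatment noise: re-emit an already-present category at a
    # date in [its first occurrence, outcome), never altering extraction.
    for _ in range(noise.max_extra_events):
        if rng.random() >= noise.p_duplicate_event:
            continue
        cat = alloc.steps[rng.randrange(len(alloc.steps))]
        lo = first_date[cat]
        hi = (amp_date - _dt.timedelta(days=1)) if amp_date else (
            dates[-1] + _dt.timedelta(days=30)
        )
        if hi < lo:
            continue
        d = lo + _dt.timedelta(days=rng.randint(0, (hi - lo).days))
        events.append(ClinicalEvent(person_id, cat, d))

    # Post-outcome noise.
    for _ in range(noise.max_extra_events):
        if rng.random() >= noise.p_post_outcome_event:
            continue
        if amp_date is not None:
            code = list(TreatmentCode)[rng.randrange(len(TreatmentCode))]
            d = amp_date + _dt.timedelta(days=1 + rng.randint(0, 90))
        else:
            code = alloc.steps[rng.randrange(len(alloc.steps))]
            d = dates[-1] + _dt.timedelta(days=1 + rng.randint(0, 90))
        events.append(ClinicalEvent(person_id, code, d))

    events.sort(key=lambda e: (e.date, e.code_value))
    return events


def generate_cohort(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[list[ClinicalEvent], list[PatientAttributes]]:
    """Generate (events, persons) realizing the spec's allocation table.

    ``seed`` overrides ``spec.seed``.  The contract: extraction over the
    output yields, for every allocation, exactly ``n_patients`` patients
    whose sequence equals ``steps`` with outcome ``outcome``.
    """
    spec.validate()
    rng = random.Random(spec.seed if seed is None else seed)
    events: list[ClinicalEvent] = []
    persons: list[PatientAttributes] = []
    idx = 0
    for alloc in spec.allocations:
        for _ in range(alloc.n_patients):
            person_id = f"{spec.dataset_label}-{idx:06d}"
            idx += 1
            events.extend(_generate_patient_events(rng, spec, person_id, alloc))
            persons.append(_draw_attributes(rng, spec, person_id, alloc.attributes))
    return events, persons


# ---------------------------------------------------------------------------
# Spec (de)serialization — round-trippable plain-dict form for YAML configs.

def spec_to_dict(spec: SyntheticSpec) -> dict:
    def alloc_to_dict(a: PathwayAllocation) -> dict:
        out: dict = {
            "steps": [s.value for s in a.steps],
            "outcome": a.outcome.value,
            "n_patients": a.n_patients,
        }
        if a.attributes is not None:
            t = a.attributes
            attrs: dict = {}
            if t.age is not None:
                attrs["age"] = list(t.age) if isinstance(t.age, tuple) else t.age
            for name in ("gender", "race", "smoker"):
                if getattr(t, name) is not None:
                    attrs[name] = getattr(t, name)
            if t.comorbidities is not None:
                attrs["comorbidities"] = sorted(c.value for c in t.comorbidities)
            out["attributes"] = attrs
        return out

    return {
        "dataset_label": spec.dataset_label,
        "allocations": [alloc_to_dict(a) for a in spec.allocations],
        "noise": {
            "p_duplicate_event": spec.noise.p_duplicate_event,
            "p_post_outcome_event": spec.noise.p_post_outcome_event,
            "max_extra_events": spec.noise.max_extra_events,
        },
        "confounder_prevalence": {c.value: p for c, p in spec.confounder_prevalence.items()},
        "smoker_prevalence": spec.smoker_prevalence,
        "date_start": spec.date_start.isoformat(),
        "mean_gap_days": spec.mean_gap_days,
        "seed": spec.seed,
    }


def spec_from_dict(payload: dict) -> SyntheticSpec:
    def alloc_from_dict(d: dict) -> PathwayAllocation:
        attrs = None
        if "attributes" in d:
            raw = d["attributes"]
            age = raw.get("age")
            if isinstance(age, list):
                age = tuple(age)
            com = raw.get("comorbidities")
            attrs = AttributeTemplate(
                age=age,
                gender=raw.get("gender"),
                race=raw.get("race"),
                smoker=raw.get("smoker"),
                comorbidities=None if com is None else frozenset(Comorbidity(c) for c in com),
            )
        return PathwayAllocation(
            steps=tuple(TreatmentCode(s) for s in d["steps"]),
            outcome=OutcomeLabel(d["outcome"]),
            n_patients=int(d["n_patients"]),
            attributes=attrs,
        )

    noise = payload.get("noise", {})
    return SyntheticSpec(
        dataset_label=payload["dataset_label"],
        allocations=tuple(alloc_from_dict(a) for a in payload["allocations"]),
        noise=NoiseSettings(
            p_duplicate_event=noise.get("p_duplicate_event", 0.25),
            p_post_outcome_event=noise.get("p_post_outcome_event", 0.25),
            max_extra_events=noise.get("max_extra_events", 3),
        ),
        confounder_prevalence={
            Comorbidity(c): p for c, p in payload.get("confounder_prevalence", {}).items()
        },
        smoker_prevalence=payload.get("smoker_prevalence", DEFAULT_SMOKER_PREVALENCE),
        date_start=_dt.date.fromisoformat(payload.get("date_start", "2015-01-01")),
        mean_gap_days=payload.get("mean_gap_days", 45.0),
        seed=int(payload.get("seed", 0)),
    )


def load_spec(path) -> SyntheticSpec:
    import yaml
    from pathlib import Path

    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_spec(spec: SyntheticSpec, path) -> None:
    import yaml
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
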