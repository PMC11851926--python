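"""Reduce raw event logs to one treatment sequence per eligible patient.

Rules, in order:

1. A patient's outcome is AMPUTATION iff any of their events is an
   amputation event; otherwise NON_AMPUTATION.
2. For amputation patients, only treatment events dated strictly before
   the FIRST amputation date count (same-day events cannot establish
   precedence at day resolution); non-amputation patients contribute
   their whole record.
3. Each treatment category enters the sequence once, at its first
   qualifying occurrence, in chronological order.  Same-date ties
   between different treatments are broken by the canonical category
   order (the enum definition order), so extraction is deterministic
   and independent of input row order.
4. Patients whose resulting step list is empty (no treatment before the
   outcome) are excluded from the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    ClinicalEvent,
    OutcomeLabel,
    PatientAttributes,
    TreatmentCode,
    TreatmentSequence,
)

#: Sentinel returned by extract_sequence for ineligible patients.
EXCLUDED = object()


@dataclass
class ExtractionReport:
    """Bookkeeping for cohort construction.

    Invariant: n_input_patients = n_excluded_no_treatment + n_amputation
    + n_non_amputation.  Patients present in the event log but absent
    from the person table are retained for pathway statistics and listed
    in ``persons_missing_attributes`` (they drop out only of confounder
    stratification).
    """

    n_input_patients: int = 0
    n_excluded_no_treatment: int = 0
    n_amputation: int = 0
    n_non_amputation: int = 0
    persons_missing_attributes: list = field(default_factory=list)

    def check(self) -> None:
        total = self.n_excluded_no_treatment + self.n_amputation + self.n_non_amputation
        if total != self.n_input_patients:
            raise AssertionError("inconsistent extraction report")


def _require_single_person(events: list[ClinicalEvent]) -> str:
    ids = {e.person_id for e in events}
    if len(ids) != 1:
        raise ValueError(f"events span multiple person_ids: {sorted(ids)}")
    return next(iter(ids))


def assign_outcome(events: list[ClinicalEvent]) -> OutcomeLabel:
    """AMPUTATION iff any event is an amputation event."""
    if not events:
        raise ValueError("events must be non-empty")
    _require_single_person(events)
    if any(e.is_outcome for e in events):
        return OutcomeLabel.AMPUTATION
    return OutcomeLabel.NON_AMPUTATION


def _sort_key(event: ClinicalEvent):
    # Canonical tie order for same-date treatments; amputation events sort
    # after treatments on their date (irrelevant to the strictly-before
    # truncation rule, but keeps sorting total).
    rank = (
        event.code.canonical_rank
        if isinstance(event.code, TreatmentCode)
        else len(TreatmentCode)
    )
    return (event.date, rank)


def extract_sequence(events: list[ClinicalEvent]):
    """First-occurrence, outcome-truncated sequence for one patient.

    Returns a :class:`TreatmentSequence`, or :data:`EXCLUDED` when the
    patient has no treatment strictly before their first amputation (or
    no treatment at all).
    """
    if not events:
        raise ValueError("events must be non-empty")
    person_id = _require_single_person(events)
    outcome = assign_outcome(events)
    ordered = sorted(events, key=_sort_key)
    first_amp = min((e.date for e in ordered if e.is_outcome), default=None)

    steps: list[TreatmentCode] = []
    seen: set[TreatmentCode] = set()
    for ev in ordered:
        if ev.is_outcome:
            continue
        if first_amp is not None and ev.date >= first_amp:
            continue
        if ev.code not in seen:
            seen.add(ev.code)
            steps.append(ev.code)
    if not steps:
        return EXCLUDED
    return TreatmentSequence(person_id=person_id, outcome=outcome, steps=tuple(steps))


def build_cohort(
    events: list[ClinicalEvent],
    persons: list[PatientAttributes] | None = None,
) -> tuple[list[TreatmentSequence], ExtractionReport]:
    """Extract one sequence per eligible patient over a whole event log.

    Sequences are returned in sorted person_id order, so the result is
    independent of input row order.
    """
    by_person: dict[str, list[ClinicalEvent]] = {}
    for ev in events:
        by_person.setdefault(ev.person_id, []).append(ev)

    known_ids = {p.person_id for p in persons} if persons is not None else None
    report = ExtractionReport(n_input_patients=len(by_person))
    sequences: list[TreatmentSequence] = []
    for pid in sorted(by_person):
        result = extract_sequence(by_person[pid])
        if result is EXCLUDED:
            report.n_excluded_no_treatment += 1
            continue
        if result.outcome is OutcomeLabel.AMPUTATION:
            report.n_amputation += 1
        else:
            report.n_non_amputation += 1
        if known_ids is not None and pid not in known_ids:
            report.persons_missing_attributes.append(pid)
        sequences.append(result)
    report.check()
    return sequences, report
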