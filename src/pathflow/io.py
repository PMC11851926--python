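"""Readers and writers for the delimited event/person tables and outputs.

All tables are plain delimited text with a header row.  The delimiter is
inferred from the file extension (``.tsv``/``.tab`` → tab, otherwise
comma) unless given explicitly.  Strict parsing is the default: malformed
rows raise with their line number.  Lenient mode logs and skips them —
silent data loss is worse than failure, so lenient is opt-in.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    AMPUTATION_CODE,
    ClinicalEvent,
    Comorbidity,
    OutcomeLabel,
    PatientAttributes,
    TreatmentCode,
    parse_event_code,
)

logger = logging.getLogger(__name__)

#: Default event-table column names; remap via the ``columns`` argument.
DEFAULT_EVENT_COLUMNS = ("person_id", "event_code", "event_date")

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


class ConfigurationError(ValueError):
    """A required column is missing or the header is malformed."""


class RowParseError(ValueError):
    """A data row failed to parse; message names the 1-based line number."""


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _parse_bool(token: str, line_no: int, column: str) -> bool:
    norm = token.strip().lower()
    if norm in _TRUE_TOKENS:
        return True
    if norm in _FALSE_TOKENS:
        return False
    raise RowParseError(f"line {line_no}: cannot parse boolean {token!r} in column {column!r}")


def read_events(
    path: str | Path,
    delimiter: str | None = None,
    columns: Sequence[str] = DEFAULT_EVENT_COLUMNS,
    strict: bool = True,
) -> list[ClinicalEvent]:
    """Read a clinical event table; one ClinicalEvent per row, file order.

    ``columns`` maps the (person_id, event_code, event_date) roles onto
    the file's header names.  In strict mode an unknown code or bad date
    raises :class:`RowParseError` naming the line; in lenient mode the
    row is logged and skipped.
    """
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    id_col, code_col, date_col = columns
    events: list[ClinicalEvent] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in columns if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {missing}; header is {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                code = parse_event_code(row[code_col])
                date = _dt.date.fromisoformat(row[date_col].strip())
            except (ValueError, AttributeError) as exc:
                if strict:
                    raise RowParseError(f"{path}: line {line_no}: {exc}") from exc
                logger.warning("%s: line %d skipped: %s", path, line_no, exc)
                continue
            events.append(ClinicalEvent(person_id=row[id_col].strip(), code=code, date=date))
    return events


def write_events(events: Iterable[ClinicalEvent], path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(DEFAULT_EVENT_COLUMNS)
        for ev in events:
            writer.writerow([ev.person_id, ev.code_value, ev.date.isoformat()])


_PERSON_BASE_COLUMNS = ("person_id", "age", "gender", "race", "smoker")


def read_persons(path: str | Path, delimiter: str | None = None) -> list[PatientAttributes]:
    """Read a person attribute table.

    Requires person_id, age, gender, race, smoker plus one boolean column
    per comorbidity flag (named by the lowercase flag).  Duplicate
    person_id or negative age is always an error.
    """
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    persons: list[PatientAttributes] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in _PERSON_BASE_COLUMNS if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {missing}; header is {header}"
            )
        comorbidity_cols = [c for c in Comorbidity if c.value in header]
        for line_no, row in enumerate(reader, start=2):
            pid = row["person_id"].strip()
            if pid in seen:
                raise RowParseError(f"{path}: line {line_no}: duplicate person_id {pid!r}")
            seen.add(pid)
            try:
                age = int(row["age"])
            except ValueError as exc:
                raise RowParseError(f"{path}: line {line_no}: bad age {row['age']!r}") from exc
            if age < 0:
                raise RowParseError(f"{path}: line {line_no}: negative age {age}")
            flags = frozenset(
                c for c in comorbidity_cols if _parse_bool(row[c.value], line_no, c.value)
            )
            persons.append(
                PatientAttributes(
                    person_id=pid,
                    age=age,
                    gender=row["gender"].strip(),
                    race=row["race"].strip(),
                    smoker=_parse_bool(row["smoker"], line_no, "smoker"),
                    comorbidities=flags,
                )
            )
    return persons


def write_persons(persons: Iterable[PatientAttributes], path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    header = list(_PERSON_BASE_COLUMNS) + [c.value for c in Comorbidity]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(header)
        for p in persons:
            writer.writerow(
                [p.person_id, p.age, p.gender, p.race, int(p.smoker)]
                + [int(c in p.comorbidities) for c in Comorbidity]
            )


_MAX_STAGES = len(TreatmentCode)
_SEQUENCE_COLUMNS = ["person_id", "outcome"] + [f"step{i}" for i in range(1, _MAX_STAGES + 1)]


def write_sequences(sequences, path: str | Path, delimiter: str | None = None) -> None:
    """Write extracted sequences as person_id, outcome, step1..step6."""
    from .model import TreatmentSequence  # noqa: F401  (documented type)

    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_SEQUENCE_COLUMNS)
        for seq in sequences:
            steps = [s.value for s in seq.steps]
            steps += [""] * (_MAX_STAGES - len(steps))
            writer.writerow([seq.person_id, seq.outcome.value] + steps)


def read_sequences(path: str | Path, delimiter: str | None = None):
    from .model import TreatmentSequence

    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    out = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in _SEQUENCE_COLUMNS[:2] if c not in header]
        if missing:
            raise ConfigurationError(f"{path}: missing column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            steps = []
            for i in range(1, _MAX_STAGES + 1):
                token = (row.get(f"step{i}") or "").strip()
                if token:
                    code = parse_event_code(token)
                    if code == AMPUTATION_CODE:
                        raise RowParseError(f"{path}: line {line_no}: amputation is not a step")
                    steps.append(code)
            out.append(
                TreatmentSequence(
                    person_id=row["person_id"].strip(),
                    outcome=OutcomeLabel(row["outcome"].strip().lower()),
                    steps=tuple(steps),
                )
            )
    return out


def write_pathway_table(table, path: str | Path, delimiter: str | None = None) -> None:
    """Write a pathway table: stage1..stage6, outcome, count, rate_percent.

    Rows are ordered by descending rate (then descending count), ties
    broken lexicographically by pathway, so output is deterministic.
    """
    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    header = [f"stage{i}" for i in range(1, _MAX_STAGES + 1)] + ["outcome", "count", "rate_percent"]
    rows = sorted(
        table.rows,
        key=lambda r: (
            -(r.rate_percent if r.rate_percent is not None else 0.0),
            -r.count,
            tuple(s.value for s in r.steps),
            r.outcome.value,
        ),
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(header)
        for r in rows:
            stages = [s.value for s in r.steps]
            stages += [""] * (_MAX_STAGES - len(stages))
            rate = "" if r.rate_percent is None else f"{r.rate_percent:.2f}"
            writer.writerow(stages + [r.outcome.value, r.count, rate])


def read_pathway_table(path: str | Path, dataset_label: str = "", delimiter: str | None = None):
    """Round-trip reader for :func:`write_pathway_table` output."""
    from .stats import PathwayRow, PathwayTable

    path = Path(path)
    delim = _infer_delimiter(path, delimiter)
    rows = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for line_no, row in enumerate(reader, start=2):
            steps = []
            for i in range(1, _MAX_STAGES + 1):
                token = (row.get(f"stage{i}") or "").strip()
                if token:
                    steps.append(TreatmentCode(token))
            rate_token = (row.get("rate_percent") or "").strip()
            rows.append(
                PathwayRow(
                    steps=tuple(steps),
                    outcome=OutcomeLabel(row["outcome"].strip()),
                    count=int(row["count"]),
                    rate_percent=float(rate_token) if rate_token else None,
                )
            )
    sizes: dict[OutcomeLabel, int] = {}
    for r in rows:
        sizes[r.outcome] = sizes.get(r.outcome, 0) + r.count
    return PathwayTable(dataset_label=dataset_label, rows=rows, cohort_sizes=sizes)
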