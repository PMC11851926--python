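"""Pathway counting, cohort-level normalization and dominance tables.

Cohort-level normalization divides each pathway's count by the total
number of sequences in its outcome cohort (one sequence per included
patient), giving a percentage rate on the 0–100 scale, rounded half away
from zero to two decimals.  Because amputations are rare relative to
non-amputations, rates are only ever compared within-normalized cohorts,
never as raw counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from decimal import Decimal
from typing import Iterable, Sequence

from .model import (
    OutcomeLabel,
    TreatmentCode,
    TreatmentSequence,
    pathway_key,
    percentage,
)


@dataclass(frozen=True)
class PathwayRow:
    steps: tuple
    outcome: OutcomeLabel
    count: int
    rate_percent: float | None = None


@dataclass(frozen=True)
class PathwayTable:
    """Per-(pathway, outcome) counts and cohort-normalized rates.

    Invariants (checked by :meth:`validate`): per outcome, counts sum to
    the cohort size; once normalized, rates sum to 100 within rounding
    tolerance (±0.005 per row) and each rate equals
    100·count/cohort_size rounded to 2 decimals.
    """

    dataset_label: str
    rows: tuple
    cohort_sizes: dict

    def __init__(self, dataset_label: str, rows: Iterable[PathwayRow], cohort_sizes: dict):
        object.__setattr__(self, "dataset_label", dataset_label)
        object.__setattr__(self, "rows", tuple(rows))
        object.__setattr__(self, "cohort_sizes", dict(cohort_sizes))

    @property
    def normalized(self) -> bool:
        return all(r.rate_percent is not None for r in self.rows)

    def rate(self, steps: Sequence[TreatmentCode], outcome: OutcomeLabel) -> float:
        """Rate of one pathway in one cohort; 0.0 when absent."""
        steps = tuple(steps)
        for r in self.rows:
            if r.steps == steps and r.outcome == outcome:
                if r.rate_percent is None:
                    raise ValueError("table is not normalized")
                return r.rate_percent
        return 0.0

    def count(self, steps: Sequence[TreatmentCode], outcome: OutcomeLabel) -> int:
        steps = tuple(steps)
        for r in self.rows:
            if r.steps == steps and r.outcome == outcome:
                return r.count
        return 0

    def validate(self) -> None:
        totals: dict[OutcomeLabel, int] = {}
        for r in self.rows:
            totals[r.outcome] = totals.get(r.outcome, 0) + r.count
        for outcome, total in totals.items():
            if total != self.cohort_sizes.get(outcome):
                raise AssertionError(
                    f"{outcome}: counts sum to {total}, cohort size is "
                    f"{self.cohort_sizes.get(outcome)}"
                )
        if self.normalized:
            for outcome in totals:
                rows = [r for r in self.rows if r.outcome == outcome]
                rate_sum = float(sum(Decimal(str(r.rate_percent)) for r in rows))
                if abs(rate_sum - 100.0) > 0.05 * len(rows) + 1e-9:
                    raise AssertionError(f"{outcome}: rates sum to {rate_sum}")

    def to_frame(self):
        """Long-format pandas view (stage1..stage6, outcome, count, rate)."""
        import pandas as pd

        max_stages = len(TreatmentCode)
        records = []
        for r in self.rows:
            rec = {f"stage{i + 1}": (r.steps[i].value if i < len(r.steps) else "")
                   for i in range(max_stages)}
            rec.update(outcome=r.outcome.value, count=r.count, rate_percent=r.rate_percent)
            records.append(rec)
        return pd.DataFrame.from_records(records)


def count_pathways(
    sequences: Iterable[TreatmentSequence], dataset_label: str = ""
) -> PathwayTable:
    """Exact multiset counts of (steps, outcome) over the cohort.

    Cohort sizes are the number of sequences per outcome (one sequence
    per included patient).
    """
    sequences = list(sequences)
    counter = Counter((seq.steps, seq.outcome) for seq in sequences)
    sizes: dict[OutcomeLabel, int] = {}
    for seq in sequences:
        sizes[seq.outcome] = sizes.get(seq.outcome, 0) + 1
    rows = [
        PathwayRow(steps=steps, outcome=outcome, count=n)
        for (steps, outcome), n in sorted(
            counter.items(), key=lambda kv: (-kv[1], pathway_key(kv[0][0]), kv[0][1].value)
        )
    ]
    return PathwayTable(dataset_label=dataset_label, rows=rows, cohort_sizes=sizes)


def cohort_normalize(table: PathwayTable) -> PathwayTable:
    """Fill rate_percent = 100·count/cohort_size, 2 dp, half away from zero."""
    for outcome in {r.outcome for r in table.rows}:
        if table.cohort_sizes.get(outcome, 0) <= 0:
            raise ValueError(f"cohort size for {outcome} is zero but rows exist")
    rows = [
        replace(r, rate_percent=percentage(r.count, table.cohort_sizes[r.outcome]))
        for r in table.rows
    ]
    rows.sort(key=lambda r: (-r.rate_percent, pathway_key(r.steps), r.outcome.value))
    out = PathwayTable(table.dataset_label, rows, table.cohort_sizes)
    out.validate()
    return out


def dominant_pathways(
    table: PathwayTable, favored: OutcomeLabel, top_k: int | None = None
) -> list[PathwayRow]:
    """Pathways strictly more prevalent in the favored cohort.

    A pathway qualifies when its rate in ``favored`` strictly exceeds the
    same pathway's rate in the other cohort (0 when absent there).
    Sorted by favored rate descending, ties lexicographic by pathway.
    """
    if not table.normalized:
        raise ValueError("dominant_pathways requires a normalized table")
    other = (
        OutcomeLabel.NON_AMPUTATION
        if favored is OutcomeLabel.AMPUTATION
        else OutcomeLabel.AMPUTATION
    )
    out = [
        r
        for r in table.rows
        if r.outcome == favored and r.rate_percent > table.rate(r.steps, other)
    ]
    out.sort(key=lambda r: (-r.rate_percent, pathway_key(r.steps)))
    return out if top_k is None else out[:top_k]


def compare_datasets(
    tables: Sequence[PathwayTable],
    steps: Sequence[TreatmentCode],
    outcome: OutcomeLabel,
    strict: bool = True,
) -> list[tuple[str, float]]:
    """One (dataset_label, rate) row per table, preserving table order.

    With ``strict`` (default), at least two tables with distinct labels
    are required — a single dataset is not a comparison.
    """
    labels = [t.dataset_label for t in tables]
    if strict and len(set(labels)) < 2:
        raise ValueError("compare_datasets needs >= 2 tables with distinct dataset_labels")
    steps = tuple(steps)
    return [(t.dataset_label, t.rate(steps, outcome)) for t in tables]
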