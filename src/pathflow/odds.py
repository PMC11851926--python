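"""Per-pathway 2×2 contingency tables, odds ratios, and probabilities.

For a pathway P the contingency table counts patients whose full
extracted sequence equals P (exact, ordered match) against outcome:

    a = amputation patients following P      b = non-amputation following P
    c = amputation patients not following P  d = non-amputation not following P

OR = (a·d)/(b·c); OR > 1 means the pathway is associated with higher
amputation odds.  When any cell is zero the Haldane–Anscombe correction
(add 0.5 to every cell) is applied and flagged.  The odds→probability
conversion p = OR/(1+OR) maps the ratio onto [0, 1] with p(1) = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import NormalDist
from typing import Iterable, Literal, Sequence

from .model import OutcomeLabel, TreatmentCode, TreatmentSequence, pathway_key


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # amputation, pathway
    b: int  # non-amputation, pathway
    c: int  # amputation, other
    d: int  # non-amputation, other

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be >= 0")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class OddsResult:
    steps: tuple
    table: ContingencyTable
    odds_ratio: float
    probability: float
    corrected: bool


def odds_ratio(table: ContingencyTable) -> float:
    """(a·d)/(b·c), with the 0.5 correction when any cell is zero."""
    value, _ = odds_ratio_corrected(table)
    return value


def odds_ratio_corrected(table: ContingencyTable) -> tuple[float, bool]:
    if table.a == table.b == table.c == table.d == 0:
        raise ValueError("odds ratio undefined: all four cells are zero")
    if table.has_zero_cell:
        a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
        return (a * d) / (b * c), True
    return (table.a * table.d) / (table.b * table.c), False


def or_to_probability(odds_ratio: float) -> float:
    """p = OR/(1+OR); monotone, p(0)=0, p(1)=0.5, p(∞)=1."""
    if odds_ratio < 0:
        raise ValueError("odds ratio must be >= 0")
    if math.isinf(odds_ratio):
        return 1.0
    return odds_ratio / (1.0 + odds_ratio)


def contingency_for_pathway(
    sequences: Iterable[TreatmentSequence], steps: Sequence[TreatmentCode]
) -> ContingencyTable:
    """Exact full-sequence membership counts per outcome."""
    steps = tuple(steps)
    a = b = c = d = 0
    for seq in sequences:
        follows = seq.steps == steps
        if seq.outcome is OutcomeLabel.AMPUTATION:
            a += follows
            c += not follows
        else:
            b += follows
            d += not follows
    return ContingencyTable(a=a, b=b, c=c, d=d)


def confidence_interval(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float]:
    """Woolf (log-normal) CI for the odds ratio; optional extra, not part
    of the standard output."""
    value, corrected = odds_ratio_corrected(table)
    cells = (table.a, table.b, table.c, table.d)
    if corrected:
        cells = tuple(x + 0.5 for x in cells)
    se = math.sqrt(sum(1.0 / x for x in cells))
    z = NormalDist().inv_cdf(1 - alpha / 2)
    return value * math.exp(-z * se), value * math.exp(z * se)


def odds_table(
    sequences: Iterable[TreatmentSequence],
    pathways: Sequence[Sequence[TreatmentCode]] | None = None,
    direction_filter: Literal["below_1", "above_1", "all"] = "all",
) -> list[OddsResult]:
    """One OddsResult per pathway, filtered by OR direction.

    ``pathways=None`` analyzes every distinct pathway observed in the
    cohort.  Results are sorted by odds ratio descending, ties broken
    lexicographically by pathway.
    """
    sequences = list(sequences)
    if pathways is None:
        seen = sorted({seq.steps for seq in sequences}, key=pathway_key)
        pathways = seen
    results = []
    for steps in pathways:
        steps = tuple(steps)
        table = contingency_for_pathway(sequences, steps)
        value, corrected = odds_ratio_corrected(table)
        results.append(
            OddsResult(
                steps=steps,
                table=table,
                odds_ratio=value,
                probability=or_to_probability(value),
                corrected=corrected,
            )
        )
    if direction_filter == "below_1":
        results = [r for r in results if r.odds_ratio < 1]
    elif direction_filter == "above_1":
        results = [r for r in results if r.odds_ratio > 1]
    elif direction_filter != "all":
        raise ValueError(f"unknown direction_filter {direction_filter!r}")
    results.sort(key=lambda r: (-r.odds_ratio, pathway_key(r.steps)))
    return results


def write_odds_table(results: Iterable[OddsResult], path, delimiter: str | None = None) -> None:
    """Delimited output: pathway, a, b, c, d, odds_ratio, probability, corrected."""
    import csv
    from pathlib import Path

    from .model import format_pathway, round_half_up

    path = Path(path)
    delim = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["pathway", "a", "b", "c", "d", "odds_ratio", "probability", "corrected"])
        for r in results:
            t = r.table
            writer.writerow(
                [
                    format_pathway(r.steps, sep=" -> "),
                    t.a,
                    t.b,
                    t.c,
                    t.d,
                    f"{r.odds_ratio:.4f}",
                    f"{round_half_up(r.probability, 2):.2f}",
                    int(r.corrected),
                ]
            )
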