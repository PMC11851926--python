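"""Confounder-stratified re-analysis.

A stratum is a sub-cohort selected by a single predicate over patient
attributes — an age cut (>t or ≤t with the study's thresholds 50, 65,
80, arbitrary values allowed), gender, race, smoking status, or a
comorbidity flag.  Filters only select sequences, never mutate them, so
every per-stratum statistic equals the unstratified pipeline run on the
pre-filtered cohort.  Patients whose attributes are missing from the
person table are dropped from every stratum (with a logged count); an
unknown race/gender value simply matches nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .model import Comorbidity, OutcomeLabel, PatientAttributes, TreatmentSequence
from .sankey import SankeyGraph, build_graph, export_graph, normalize_graph
from .stats import PathwayTable, cohort_normalize, count_pathways

logger = logging.getLogger(__name__)

#: Age thresholds used by the study's strata.
STUDY_AGE_THRESHOLDS = (50, 65, 80)
STUDY_GENDERS = ("male", "female")
STUDY_RACES = ("white", "black", "asian")


class FilterKind(Enum):
    ALL = "all"  # identity predicate: the full cohort row
    AGE_GT = "age_gt"
    AGE_LE = "age_le"
    GENDER_EQ = "gender_eq"
    RACE_EQ = "race_eq"
    SMOKER = "smoker"
    COMORBIDITY = "comorbidity"


@dataclass(frozen=True)
class ConfounderFilter:
    kind: FilterKind
    value: "int | str | Comorbidity | None" = None

    def __post_init__(self) -> None:
        if self.kind in (FilterKind.AGE_GT, FilterKind.AGE_LE):
            if not isinstance(self.value, int):
                raise ValueError(f"{self.kind.value} needs an integer threshold")
        elif self.kind in (FilterKind.GENDER_EQ, FilterKind.RACE_EQ):
            if not isinstance(self.value, str):
                raise ValueError(f"{self.kind.value} needs a string value")
        elif self.kind is FilterKind.COMORBIDITY:
            if not isinstance(self.value, Comorbidity):
                raise ValueError("comorbidity filter needs a Comorbidity flag")

    def matches(self, person: PatientAttributes) -> bool:
        if self.kind is FilterKind.ALL:
            return True
        if self.kind is FilterKind.AGE_GT:
            return person.age > self.value
        if self.kind is FilterKind.AGE_LE:
            return person.age <= self.value
        if self.kind is FilterKind.GENDER_EQ:
            return person.gender.lower() == self.value.lower()
        if self.kind is FilterKind.RACE_EQ:
            return person.race.lower() == self.value.lower()
        if self.kind is FilterKind.SMOKER:
            return person.smoker
        if self.kind is FilterKind.COMORBIDITY:
            return self.value in person.comorbidities
        raise AssertionError(self.kind)

    def describe(self) -> str:
        if self.kind is FilterKind.ALL:
            return "full cohort"
        if self.kind is FilterKind.AGE_GT:
            return f"age > {self.value}"
        if self.kind is FilterKind.AGE_LE:
            return f"age <= {self.value}"
        if self.kind is FilterKind.SMOKER:
            return "smoker"
        if self.kind is FilterKind.COMORBIDITY:
            return self.value.value
        return f"{self.kind.value.split('_')[0]} {self.value}"

    @property
    def slug(self) -> str:
        return self.describe().replace(" ", "_").replace(">", "gt").replace("<=", "le")


def paper_strata() -> list[ConfounderFilter]:
    """The study's 19 strata: full cohort, 6 comorbidities, 6 age cuts,
    2 genders, 3 races, smokers."""
    out = [ConfounderFilter(FilterKind.ALL)]
    out += [ConfounderFilter(FilterKind.COMORBIDITY, c) for c in Comorbidity]
    for t in STUDY_AGE_THRESHOLDS:
        out.append(ConfounderFilter(FilterKind.AGE_GT, t))
        out.append(ConfounderFilter(FilterKind.AGE_LE, t))
    out += [ConfounderFilter(FilterKind.GENDER_EQ, g) for g in STUDY_GENDERS]
    out += [ConfounderFilter(FilterKind.RACE_EQ, r) for r in STUDY_RACES]
    out.append(ConfounderFilter(FilterKind.SMOKER))
    return out


def apply_filter(
    persons: Iterable[PatientAttributes],
    sequences: Iterable[TreatmentSequence],
    filt: ConfounderFilter,
) -> list[TreatmentSequence]:
    """Sequences of exactly the patients satisfying the predicate.

    Sequences without a person record are dropped (logged once).
    """
    by_id = {p.person_id: p for p in persons}
    kept: list[TreatmentSequence] = []
    n_missing = 0
    for seq in sequences:
        person = by_id.get(seq.person_id)
        if person is None:
            n_missing += 1
            continue
        if filt.matches(person):
            kept.append(seq)
    if n_missing:
        logger.warning(
            "%d sequence(s) dropped from stratum %r: no person record",
            n_missing, filt.describe(),
        )
    return kept


@dataclass
class StratumSummary:
    filter: ConfounderFilter
    description: str
    n_amputation: int
    n_non_amputation: int
    table: PathwayTable
    graph: SankeyGraph | None = None
    graph_path: Path | None = None

    @property
    def n_total(self) -> int:
        return self.n_amputation + self.n_non_amputation


def stratified_run(
    sequences: Iterable[TreatmentSequence],
    persons: Iterable[PatientAttributes],
    filters: Sequence[ConfounderFilter],
    out_dir: "Path | str | None" = None,
    dataset_label: str = "",
) -> list[StratumSummary]:
    """Re-run counting, normalization and graph building per stratum.

    With ``out_dir``, each stratum gets a subdirectory holding its
    pathway table and Sankey JSON; empty strata get a zero summary row
    and no graph.
    """
    from .io import write_pathway_table

    sequences = list(sequences)
    persons = list(persons)
    out_dir = Path(out_dir) if out_dir is not None else None
    summaries: list[StratumSummary] = []
    for filt in filters:
        sub = apply_filter(persons, sequences, filt)
        n_amp = sum(1 for s in sub if s.outcome is OutcomeLabel.AMPUTATION)
        n_non = len(sub) - n_amp
        table = count_pathways(sub, dataset_label=f"{dataset_label}:{filt.slug}")
        graph = None
        graph_path = None
        if sub:
            table = cohort_normalize(table)
            graph = normalize_graph(build_graph(sub, dataset_label=table.dataset_label))
        if out_dir is not None:
            stratum_dir = out_dir / filt.slug
            stratum_dir.mkdir(parents=True, exist_ok=True)
            write_pathway_table(table, stratum_dir / "pathways.tsv")
            if graph is not None:
                graph_path = stratum_dir / "sankey.json"
                export_graph(graph, graph_path)
        summaries.append(
            StratumSummary(
                filter=filt,
                description=filt.describe(),
                n_amputation=n_amp,
                n_non_amputation=n_non,
                table=table,
                graph=graph,
                graph_path=graph_path,
            )
        )
    return summaries


def summary_counts(summaries: Sequence[StratumSummary], dataset_label: str = ""):
    """Long-format (dataset, stratum, outcome, count) table for grouped
    bar plots, with derived age bands.

    When cumulative age strata are present, the bands 51–65 and 66–80
    are derived by differencing: n(51–65) = n(≤65) − n(≤50) and
    n(66–80) = n(≤80) − n(≤65).  Inconsistent cumulative counts (a wider
    ≤-stratum smaller than a narrower one) raise ValueError.
    """
    import pandas as pd

    records = []
    by_age_le: dict[int, StratumSummary] = {}
    for s in summaries:
        records.append((dataset_label, s.description, "amputation", s.n_amputation))
        records.append((dataset_label, s.description, "non_amputation", s.n_non_amputation))
        if s.filter.kind is FilterKind.AGE_LE:
            by_age_le[s.filter.value] = s
    for lo, hi in ((50, 65), (65, 80)):
        if lo in by_age_le and hi in by_age_le:
            for attr, outcome in (
                ("n_amputation", "amputation"),
                ("n_non_amputation", "non_amputation"),
            ):
                diff = getattr(by_age_le[hi], attr) - getattr(by_age_le[lo], attr)
                if diff < 0:
                    raise ValueError(
                        f"inconsistent age strata: n(<= {hi}) < n(<= {lo}) for {outcome}"
                    )
                records.append((dataset_label, f"age {lo + 1}-{hi}", outcome, diff))
    return pd.DataFrame.from_records(
        records, columns=["dataset", "stratum", "outcome", "count"]
    )
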