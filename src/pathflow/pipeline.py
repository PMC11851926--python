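"""End-to-end orchestration: generate → extract → stats → odds → sankey
→ stratify, from one config, with a deterministic output layout.

All analytic outputs are plain text (delimited tables, JSON); re-running
with the same config and seed reproduces them byte-identically.  The run
manifest records input hashes, the seed, the package version and
per-stage row counts — everything needed to check a rerun, and nothing
(like wall-clock timestamps) that would break byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .extraction import build_cohort
from .fixtures import paper_fixture
from .io import (
    read_events,
    read_persons,
    write_events,
    write_pathway_table,
    write_persons,
    write_sequences,
)
from .model import Comorbidity
from .odds import odds_table, write_odds_table
from .sankey import build_graph, export_graph, normalize_graph
from .stats import cohort_normalize, count_pathways
from .stratify import ConfounderFilter, FilterKind, paper_strata, stratified_run, summary_counts
from .synthetic import generate_cohort, load_spec, with_seed

logger = logging.getLogger(__name__)


def parse_filter(entry: "dict | str") -> ConfounderFilter:
    """Parse a strata-config entry like {"kind": "age_le", "value": 50}."""
    if isinstance(entry, str):
        return ConfounderFilter(FilterKind(entry))
    kind = FilterKind(entry["kind"])
    value = entry.get("value")
    if kind is FilterKind.COMORBIDITY:
        value = Comorbidity(value)
    return ConfounderFilter(kind, value)


@dataclass
class RunConfig:
    out_dir: Path
    events_path: Path | None = None
    persons_path: Path | None = None
    fixture: str | None = None
    spec_path: Path | None = None
    seed: int = 0
    dataset_label: str = "cohort"
    strata: "list[ConfounderFilter] | str | None" = "paper"
    odds_filter: str = "all"
    top_k: int | None = None
    html: bool = False
    strict: bool = True

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        strata = raw.get("strata", "paper")
        if isinstance(strata, list):
            strata = [parse_filter(e) for e in strata]
        return cls(
            out_dir=Path(raw["out_dir"]),
            events_path=Path(raw["events"]) if "events" in raw else None,
            persons_path=Path(raw["persons"]) if "persons" in raw else None,
            fixture=raw.get("fixture"),
            spec_path=Path(raw["spec"]) if "spec" in raw else None,
            seed=int(raw.get("seed", 0)),
            dataset_label=raw.get("dataset_label", "cohort"),
            strata=strata,
            odds_filter=raw.get("odds_filter", "all"),
            top_k=raw.get("top_k"),
            html=bool(raw.get("html", False)),
            strict=bool(raw.get("strict", True)),
        )

    def validate(self) -> None:
        sources = [self.events_path is not None, self.fixture is not None,
                   self.spec_path is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of events/fixture/spec must be given")
        for p in (self.events_path, self.persons_path, self.spec_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # Stage 1: inputs (generate if synthetic).
    if config.fixture is not None or config.spec_path is not None:
        if config.fixture is not None:
            spec = paper_fixture(config.fixture, seed=config.seed)
        else:
            spec = with_seed(load_spec(config.spec_path), config.seed)
        logger.info("generate: fixture=%s seed=%d", config.fixture, config.seed)
        events, persons = generate_cohort(spec)
        events_path, persons_path = out / "events.csv", out / "persons.csv"
        write_events(events, events_path)
        write_persons(persons, persons_path)
    else:
        events_path = Path(config.events_path)
        events = read_events(events_path, strict=config.strict)
        if config.persons_path is not None:
            persons_path = Path(config.persons_path)
            persons = read_persons(persons_path)
        else:
            persons_path, persons = None, []
    logger.info("inputs: %d events, %d persons", len(events), len(persons))

    # Stage 2: extraction.
    sequences, report = build_cohort(events, persons or None)
    seq_path = out / "sequences.tsv"
    write_sequences(sequences, seq_path)
    logger.info(
        "extract: %d sequences (%d amputation, %d non-amputation, %d excluded)",
        len(sequences), report.n_amputation, report.n_non_amputation,
        report.n_excluded_no_treatment,
    )

    # Stage 3: pathway statistics.
    table = cohort_normalize(count_pathways(sequences, dataset_label=config.dataset_label))
    table_path = out / "pathways.tsv"
    write_pathway_table(table, table_path)

    # Stage 4: odds analysis.
    odds = odds_table(sequences, direction_filter=config.odds_filter)
    odds_path = out / "odds.csv"
    write_odds_table(odds, odds_path)

    # Stage 5: Sankey graph.
    graph = normalize_graph(build_graph(sequences, dataset_label=config.dataset_label))
    graph_path = out / "sankey.json"
    export_graph(graph, graph_path)
    if config.html:
        export_graph(graph, out / "sankey.html", format="html")

    # Stage 6: confounder stratification.
    n_strata = 0
    if config.strata is not None and persons:
        filters = paper_strata() if config.strata == "paper" else list(config.strata)
        summaries = stratified_run(
            sequences, persons, filters, out_dir=out / "strata",
            dataset_label=config.dataset_label,
        )
        summary = summary_counts(summaries, dataset_label=config.dataset_label)
        summary.to_csv(out / "strata" / "summary.tsv", sep="\t", index=False)
        n_strata = len(summaries)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "dataset_label": config.dataset_label,
        "inputs": {
            "events": {"path": str(events_path), "sha256": _sha256(events_path)},
            **(
                {"persons": {"path": str(persons_path), "sha256": _sha256(persons_path)}}
                if persons_path is not None
                else {}
            ),
        },
        "stages": {
            "events": len(events),
            "persons": len(persons),
            "sequences": len(sequences),
            "excluded_no_treatment": report.n_excluded_no_treatment,
            "pathway_rows": len(table.rows),
            "odds_rows": len(odds),
            "sankey_links": len(graph.links),
            "strata": n_strata,
        },
        "outputs": [
            str(p.relative_to(out))
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
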