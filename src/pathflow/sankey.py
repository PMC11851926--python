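"""Stage-indexed, outcome-colored Sankey flow graphs over sequences.

Each sequence contributes one unit of flow to every adjacent-pair link
along step1 → step2 → … → stepL → outcome.  Nodes are stage-indexed, so
the same treatment at stage 1 and stage 2 is two distinct nodes; the two
outcome labels live on a single terminal stage and a sequence's last
treatment links to its outcome node from whatever stage it occupies.
Flows of different outcomes through a shared node are kept as parallel
links (never merged), which is what lets the rendering color every flow
by its eventual outcome: deep amber for amputation, pine green for
non-amputation.

Two normalizations are carried on every link:

* ``cohort_value`` — raw_count divided by the size of the link's outcome
  cohort, so rare amputation flows are visible next to the much larger
  non-amputation cohort;
* ``node_value`` — cohort_value rescaled so each node's OUTGOING links
  sum to 1.  Incoming flow is conserved exactly at the raw-count level
  (everyone entering a treatment node leaves it); normalizing in- and
  out-flows of all nodes simultaneously is not generally satisfiable, so
  the sum-to-1 guarantee is defined on outgoing flows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .model import OutcomeLabel, TreatmentSequence

#: Flow colors named in the figure convention.
AMBER = "#FF8C00"  # amputation flows
PINE = "#01796F"  # non-amputation flows

OUTCOME_COLORS = {OutcomeLabel.AMPUTATION: AMBER, OutcomeLabel.NON_AMPUTATION: PINE}


@dataclass(frozen=True)
class SankeyNode:
    node_id: str
    stage: int
    label: str


@dataclass(frozen=True)
class SankeyLink:
    source: str
    target: str
    raw_count: int
    outcome: OutcomeLabel
    color: str
    cohort_value: float | None = None
    node_value: float | None = None


@dataclass(frozen=True)
class SankeyGraph:
    dataset_label: str
    nodes: tuple
    links: tuple

    def __init__(self, dataset_label: str, nodes: Iterable[SankeyNode], links: Iterable[SankeyLink]):
        object.__setattr__(self, "dataset_label", dataset_label)
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "links", tuple(links))

    @property
    def outcome_stage(self) -> int | None:
        stages = [n.stage for n in self.nodes if _is_outcome_label(n.label)]
        return stages[0] if stages else None

    def node(self, node_id: str) -> SankeyNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def validate(self) -> None:
        """Check structural invariants: unique (stage,label), no orphan
        nodes, adjacency of treatment links, raw-count flow conservation
        at internal nodes, terminal conservation, and (if normalized)
        outgoing node_values summing to 1."""
        seen = set()
        for n in self.nodes:
            key = (n.stage, n.label)
            if key in seen:
                raise AssertionError(f"duplicate node {key}")
            seen.add(key)
        touched = {l.source for l in self.links} | {l.target for l in self.links}
        for n in self.nodes:
            if n.node_id not in touched:
                raise AssertionError(f"orphan node {n.node_id}")
        by_id = {n.node_id: n for n in self.nodes}
        for l in self.links:
            src, tgt = by_id[l.source], by_id[l.target]
            if not _is_outcome_label(tgt.label) and tgt.stage != src.stage + 1:
                raise AssertionError(f"non-adjacent link {l.source} -> {l.target}")
        # raw-count conservation at internal treatment nodes
        for n in self.nodes:
            if _is_outcome_label(n.label):
                continue
            incoming = sum(l.raw_count for l in self.links if l.target == n.node_id)
            outgoing = sum(l.raw_count for l in self.links if l.source == n.node_id)
            if incoming and incoming != outgoing:
                raise AssertionError(
                    f"flow not conserved at {n.node_id}: in={incoming} out={outgoing}"
                )
        if all(l.node_value is not None for l in self.links):
            out_by_source: dict[str, float] = {}
            for l in self.links:
                out_by_source[l.source] = out_by_source.get(l.source, 0.0) + l.node_value
            for source, total in out_by_source.items():
                if abs(total - 1.0) > 1e-9:
                    raise AssertionError(f"outgoing node_values at {source} sum to {total}")


def _is_outcome_label(label: str) -> bool:
    return label in {o.label for o in OutcomeLabel}


def _treatment_node_id(stage: int, code) -> str:
    return f"s{stage}:{code.value}"


def _outcome_node_id(outcome: OutcomeLabel) -> str:
    return f"outcome:{outcome.value}"


def build_graph(
    sequences: Iterable[TreatmentSequence],
    dataset_label: str = "",
    colors: dict | None = None,
) -> SankeyGraph:
    """Aggregate sequences into a raw-count Sankey graph.

    Link identity is (source node, target node, outcome): same-outcome
    flows between the same pair of stage nodes are merged.
    """
    colors = colors or OUTCOME_COLORS
    sequences = list(sequences)
    if not sequences:
        return SankeyGraph(dataset_label, (), ())
    max_len = max(len(s.steps) for s in sequences)
    outcome_stage = max_len + 1

    counts: dict[tuple[str, str, OutcomeLabel], int] = {}
    nodes: dict[str, SankeyNode] = {}
    for seq in sequences:
        ids = [_treatment_node_id(i + 1, code) for i, code in enumerate(seq.steps)]
        for i, code in enumerate(seq.steps):
            nodes.setdefault(ids[i], SankeyNode(ids[i], i + 1, code.label))
        out_id = _outcome_node_id(seq.outcome)
        nodes.setdefault(out_id, SankeyNode(out_id, outcome_stage, seq.outcome.label))
        hops = list(zip(ids, ids[1:] + [out_id]))
        for src, tgt in hops:
            key = (src, tgt, seq.outcome)
            counts[key] = counts.get(key, 0) + 1

    ordered_nodes = sorted(nodes.values(), key=lambda n: (n.stage, n.label))
    links = [
        SankeyLink(source=src, target=tgt, raw_count=n, outcome=outcome, color=colors[outcome])
        for (src, tgt, outcome), n in counts.items()
    ]
    links.sort(key=lambda l: (nodes[l.source].stage, l.source, l.target, l.outcome.value))
    graph = SankeyGraph(dataset_label, ordered_nodes, links)
    graph.validate()
    return graph


def normalize_graph(graph: SankeyGraph, cohort_sizes: dict | None = None) -> SankeyGraph:
    """Fill cohort_value and node_value on every link.

    ``cohort_sizes`` maps OutcomeLabel → included patients; when omitted
    it is recovered from the terminal incoming raw counts (every included
    patient's sequence ends at its outcome node exactly once).
    """
    if cohort_sizes is None:
        cohort_sizes = {}
        for l in graph.links:
            if graph.node(l.target).stage == graph.outcome_stage:
                cohort_sizes[l.outcome] = cohort_sizes.get(l.outcome, 0) + l.raw_count
    links = [
        replace(l, cohort_value=l.raw_count / cohort_sizes[l.outcome]) for l in graph.links
    ]
    out_totals: dict[str, float] = {}
    for l in links:
        out_totals[l.source] = out_totals.get(l.source, 0.0) + l.cohort_value
    links = [replace(l, node_value=l.cohort_value / out_totals[l.source]) for l in links]
    out = SankeyGraph(graph.dataset_label, graph.nodes, links)
    out.validate()
    return out


def graph_to_dict(graph: SankeyGraph) -> dict:
    return {
        "dataset_label": graph.dataset_label,
        "nodes": [
            {"id": n.node_id, "stage": n.stage, "label": n.label}
            for n in sorted(graph.nodes, key=lambda n: (n.stage, n.label))
        ],
        "links": [
            {
                "source": l.source,
                "target": l.target,
                "raw_count": l.raw_count,
                "cohort_value": l.cohort_value,
                "node_value": l.node_value,
                "outcome": l.outcome.value,
                "color": l.color,
            }
            for l in sorted(
                graph.links, key=lambda l: (l.source, l.target, l.outcome.value)
            )
        ],
    }


def graph_from_dict(payload: dict) -> SankeyGraph:
    nodes = [SankeyNode(n["id"], n["stage"], n["label"]) for n in payload["nodes"]]
    links = [
        SankeyLink(
            source=l["source"],
            target=l["target"],
            raw_count=l["raw_count"],
            outcome=OutcomeLabel(l["outcome"]),
            color=l["color"],
            cohort_value=l.get("cohort_value"),
            node_value=l.get("node_value"),
        )
        for l in payload["links"]
    ]
    return SankeyGraph(payload.get("dataset_label", ""), nodes, links)


def export_graph(graph: SankeyGraph, path, format: str = "json") -> None:
    """Write the graph as deterministic JSON, or a static SVG-in-HTML view.

    Two exports of the same graph are byte-identical: nodes are ordered
    by (stage, label), links by (source, target, outcome), JSON keys are
    sorted.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(graph_to_dict(graph), sort_keys=True, indent=1) + "\n")
    elif format == "html":
        path.write_text(_render_html(graph))
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_graph(path) -> SankeyGraph:
    return graph_from_dict(json.loads(Path(path).read_text()))


def _render_html(graph: SankeyGraph, width: int = 960, height: int = 560) -> str:
    """Minimal static rendering: nodes as stage columns, links as cubic
    curves with stroke width proportional to node_value (display
    convention) falling back to raw counts when unnormalized."""
    data = graph_to_dict(graph)
    stages = sorted({n["stage"] for n in data["nodes"]}) or [1]
    margin, node_w = 60, 14
    x_for = {
        s: margin + i * ((width - 2 * margin - node_w) / max(len(stages) - 1, 1))
        for i, s in enumerate(stages)
    }
    y_pos: dict[str, float] = {}
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Treatment pathways — {graph.dataset_label}</title></head><body>",
        f"<svg width='{width}' height='{height}' xmlns='http://www.w3.org/2000/svg'>",
    ]
    for s in stages:
        col = [n for n in data["nodes"] if n["stage"] == s]
        gap = (height - 2 * margin) / max(len(col), 1)
        for j, n in enumerate(col):
            y = margin + j * gap
            y_pos[n["id"]] = y + gap * 0.35
            parts.append(
                f"<rect x='{x_for[s]:.1f}' y='{y:.1f}' width='{node_w}' "
                f"height='{gap * 0.7:.1f}' fill='#555'/>"
                f"<text x='{x_for[s] + node_w + 4:.1f}' y='{y + 12:.1f}' "
                f"font-size='11' font-family='sans-serif'>{n['label']}</text>"
            )
    by_id = {n["id"]: n for n in data["nodes"]}
    for l in data["links"]:
        weight = l["node_value"] if l["node_value"] is not None else l["raw_count"]
        w = max(1.0, 24.0 * float(weight))
        x1 = x_for[by_id[l["source"]]["stage"]] + node_w
        x2 = x_for[by_id[l["target"]]["stage"]]
        y1, y2 = y_pos[l["source"]], y_pos[l["target"]]
        mx = (x1 + x2) / 2
        parts.append(
            f"<path d='M{x1:.1f},{y1:.1f} C{mx:.1f},{y1:.1f} {mx:.1f},{y2:.1f} "
            f"{x2:.1f},{y2:.1f}' stroke='{l['color']}' stroke-width='{w:.2f}' "
            f"fill='none' opacity='0.55'/>"
        )
    parts.append("</svg></body></html>")
    return "\n".join(parts) + "\n"
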