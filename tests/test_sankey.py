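import json
from collections import Counter

from pathflow import (
    OutcomeLabel,
    build_cohort,
    build_graph,
    export_graph,
    generate_cohort,
    normalize_graph,
)
from pathflow.sankey import AMBER, PINE, graph_from_dict, graph_to_dict, load_graph

from conftest import A, L, SC, ER, AMP, NON, seq


def test_single_sequence_structure():
    g = build_graph([seq("p1", AMP, A, L)])
    assert len(g.nodes) == 3  # stage-1 A, stage-2 L, outcome
    assert len(g.links) == 2
    assert all(l.raw_count == 1 for l in g.links)
    assert all(l.color == AMBER for l in g.links)


def test_stage_indexed_nodes_distinguish_same_treatment():
    g = build_graph([seq("p1", NON, A, L), seq("p2", NON, L, A)])
    labels = {(n.stage, n.label) for n in g.nodes}
    assert (1, "Lipid lowering") in labels and (2, "Lipid lowering") in labels
    assert (1, "Antiplatelet") in labels and (2, "Antiplatelet") in labels


def test_shared_source_node_merges_same_target_same_outcome():
    g = build_graph([seq("p1", NON, A, L), seq("p2", NON, A, L), seq("p3", NON, A, ER)])
    out_links = [l for l in g.links if l.source == "s1:antiplatelet"]
    assert len(out_links) == 2
    assert {(l.target, l.raw_count) for l in out_links} == {
        ("s2:lipid_lowering", 2),
        ("s2:endovascular_revascularization", 1),
    }


def test_length_one_sequence_links_stage1_to_outcome():
    g = build_graph([seq("p1", NON, SC), seq("p2", AMP, A, L, ER)])
    short = [l for l in g.links if l.source == "s1:smoking_cessation"]
    assert len(short) == 1
    assert short[0].target == "outcome:non_amputation"


def test_link_counts_match_brute_force_pair_recount(tiny_spec):
    events, _ = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events)
    g = build_graph(sequences)
    # oracle: count every adjacent hop independently
    oracle = Counter()
    for s in sequences:
        ids = [f"s{i+1}:{c.value}" for i, c in enumerate(s.steps)]
        ids.append(f"outcome:{s.outcome.value}")
        for src, tgt in zip(ids, ids[1:]):
            oracle[(src, tgt, s.outcome)] += 1
    assert {(l.source, l.target, l.outcome): l.raw_count for l in g.links} == dict(oracle)


def test_raw_count_flow_conservation_and_terminal_totals(tiny_spec):
    events, _ = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events)
    g = normalize_graph(build_graph(sequences))
    g.validate()  # internal-node conservation + node_value sums
    for outcome, node_id in [(AMP, "outcome:amputation"), (NON, "outcome:non_amputation")]:
        into = sum(l.raw_count for l in g.links if l.target == node_id)
        assert into == sum(1 for s in sequences if s.outcome == outcome)


def test_node_normalization_examples():
    # two outgoing links with equal cohort shares -> 0.5 each
    sequences = (
        [seq(f"p{i}", NON, A, L) for i in range(2)]
        + [seq(f"q{i}", NON, A, ER) for i in range(2)]
        + [seq("r0", NON, L)]
    )
    g = normalize_graph(build_graph(sequences))
    out = {l.target: l.node_value for l in g.links if l.source == "s1:antiplatelet"}
    assert out == {"s2:lipid_lowering": 0.5, "s2:endovascular_revascularization": 0.5}
    # single outgoing link -> 1.0
    single = [l for l in g.links if l.source == "s2:lipid_lowering"]
    assert len(single) == 1 and single[0].node_value == 1.0


def test_mixed_outcome_node_values_sum_to_one_across_colors():
    # one treatment node shared by both outcomes: 1 amputation and 2
    # non-amputation patients all start with antiplatelet
    sequences = [seq("p1", AMP, A), seq("p2", NON, A), seq("p3", NON, A)]
    g = normalize_graph(build_graph(sequences))
    out = [l for l in g.links if l.source == "s1:antiplatelet"]
    assert len(out) == 2  # parallel links, never merged across outcomes
    assert {l.color for l in out} == {AMBER, PINE}
    # cohort shares are 1/1 and 2/2 -> node values 0.5 each
    assert sum(l.node_value for l in out) == 1.0


def test_export_round_trip_and_byte_identity(tmp_path, tiny_spec):
    events, _ = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events)
    g = normalize_graph(build_graph(sequences, dataset_label="tiny"))
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    export_graph(g, p1)
    export_graph(g, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert graph_to_dict(load_graph(p1)) == graph_to_dict(g)


def test_empty_graph_exports_valid_json(tmp_path):
    g = build_graph([])
    p = tmp_path / "empty.json"
    export_graph(g, p)
    payload = json.loads(p.read_text())
    assert payload["nodes"] == [] and payload["links"] == []


def test_html_export_is_a_static_svg_view(tmp_path):
    g = normalize_graph(build_graph([seq("p1", AMP, A, L), seq("p2", NON, A)]))
    p = tmp_path / "graph.html"
    export_graph(g, p, format="html")
    text = p.read_text()
    assert "<svg" in text and AMBER in text and PINE in text
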