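"""Story-graph assembly, aggregation, roles, and export round-trips."""

import itertools
import random

import networkx as nx
import pytest

from narraframe.graphs import (
    Edge,
    GraphError,
    NarrativeFramework,
    StoryGraph,
    aggregate,
    annotate_roles,
    build_story_graph,
    export_graph,
    import_graph_json,
)
from narraframe.relations import RelationInstance


def _inst(source, target, category, verb="us", sid="p1:0"):
    return RelationInstance(
        sent_id=sid, verb=verb, category=category, source=source,
        target=target, source_span=(0, 1), verb_position=1,
        target_span=(2, 3),
    )


def test_build_story_graph_hand_aggregation(alex):
    relations = (
        [_inst("Parents", "Religious institutions", "Employ or ignore",
               sid=f"p{i}:0") for i in range(3)]
        + [_inst("Schools", "Parents", "Require or resist", verb="requir")]
    )
    graph = build_story_graph(
        "Parents<->Religious institutions",
        ("Parents", "Religious institutions"), relations, alex,
    )
    assert len(graph.edges) == 2
    key1 = ("Parents", "Religious institutions", "Employ or ignore")
    key2 = ("Schools", "Parents", "Require or resist")
    assert graph.edges[key1].weight == 3
    assert graph.edges[key2].weight == 1
    assert graph.nodes["Schools"] == "institutional"


def test_build_story_graph_no_relations(alex):
    graph = build_story_graph("A<->B", ("Parents", "Exemptions"), [], alex)
    assert set(graph.nodes) == {"Parents", "Exemptions"}
    assert graph.edges == {}


def test_build_story_graph_unknown_actant_fatal(alex):
    with pytest.raises(GraphError):
        build_story_graph("A<->B", ("Parents", "Martians"), [], alex)


def test_aggregate_merges_and_conserves(alex):
    g1 = build_story_graph("c1", ("Parents", "Religious institutions"),
                           [_inst("Parents", "Religious institutions",
                                  "Employ or ignore", sid=f"a{i}:0")
                            for i in range(3)], alex)
    g2 = build_story_graph("c2", ("Parents", "Religious institutions"),
                           [_inst("Parents", "Religious institutions",
                                  "Employ or ignore", sid=f"b{i}:0")
                            for i in range(2)], alex)
    fw = aggregate([g1, g2])
    key = ("Parents", "Religious institutions", "Employ or ignore")
    assert fw.edges[key].weight == 5
    assert fw.edges[key].contexts == ("c1", "c2")
    assert fw.total_weight() == g1.total_weight() + g2.total_weight()


def test_aggregate_single_graph_identity(alex):
    g = build_story_graph("c", ("Parents", "Schools"),
                          [_inst("Schools", "Parents", "Require or resist")],
                          alex)
    fw = aggregate([g])
    assert set(fw.edges) == set(g.edges)
    assert fw.total_weight() == g.total_weight()


def test_context_dependent_relationships_stay_distinct(alex):
    """The same pair can carry different categories from different
    contexts: both edges survive aggregation."""
    g1 = build_story_graph("Exemptions<->Religious institutions",
                           ("Exemptions", "Religious institutions"),
                           [_inst("Parents", "Religious institutions",
                                  "Employ or ignore")], alex)
    g2 = build_story_graph("Children<->Religious institutions",
                           ("Children", "Religious institutions"),
                           [_inst("Parents", "Religious institutions",
                                  "Accept or reject", verb="accept")], alex)
    fw = aggregate([g1, g2])
    pair_edges = [k for k in fw.edges
                  if k[0] == "Parents" and k[1] == "Religious institutions"]
    assert sorted(k[2] for k in pair_edges) == [
        "Accept or reject", "Employ or ignore",
    ]


def _random_story_graphs(seed, alex):
    rng = random.Random(seed)
    names = alex.names
    categories = ["Employ or ignore", "Require or resist", "Seek or aver"]
    graphs = []
    for gi in range(rng.randint(1, 6)):
        pair = tuple(rng.sample(names, 2))
        relations = []
        for ri in range(rng.randint(0, 8)):
            src, tgt = rng.sample(names, 2)
            relations.append(_inst(src, tgt, rng.choice(categories),
                                   sid=f"g{gi}s{ri}:0"))
        graphs.append(build_story_graph(f"ctx{gi}", pair, relations, alex))
    return graphs


@pytest.mark.parametrize("seed", range(10))
def test_aggregation_order_invariant_and_associative(seed, alex):
    graphs = _random_story_graphs(seed, alex)
    base = aggregate(graphs)
    rng = random.Random(seed + 1)
    shuffled = list(graphs)
    rng.shuffle(shuffled)
    assert aggregate(shuffled).edges == base.edges
    assert aggregate(shuffled).total_weight() == sum(
        g.total_weight() for g in graphs)
    if len(graphs) >= 3:
        a, b, c = graphs[0], graphs[1], graphs[2:]
        left = aggregate([a] + [_fw_as_graph(aggregate([b] + c))])
        right = aggregate([_fw_as_graph(aggregate([a, b]))] + c)
        assert left.edges == right.edges


def _fw_as_graph(fw: NarrativeFramework) -> StoryGraph:
    return StoryGraph(context_label="merged", nodes=dict(fw.nodes),
                      edges=dict(fw.edges))


def test_annotate_roles(alex):
    g = build_story_graph("c", ("Parents", "Exemptions"),
                          [_inst("Parents", "Exemptions", "Seek or aver",
                                 verb="seek")], alex)
    fw = aggregate([g])
    key = ("Parents", "Exemptions", "Seek or aver")
    out = annotate_roles(fw, {key: "strategy"})
    assert out.edges[key].role == "strategy"
    unchanged = annotate_roles(fw, {})
    assert unchanged.edges == fw.edges
    with pytest.raises(GraphError):
        annotate_roles(fw, {key: "denouement"})
    with pytest.raises(GraphError):
        annotate_roles(fw, {("A", "B", "Nonesuch"): "threat"},
                       categories=["Seek or aver"])


def test_export_round_trip_json(tmp_path, alex):
    graphs = _random_story_graphs(3, alex)
    fw = annotate_roles(aggregate(graphs),
                        {k: "threat" for k in list(aggregate(graphs).edges)[:1]})
    path = tmp_path / "fw.json"
    export_graph(fw, path, "json")
    back = import_graph_json(path)
    assert back.nodes == fw.nodes
    assert back.edges == fw.edges


def test_export_graphml_and_dot_parse(tmp_path, alex):
    fw = aggregate(_random_story_graphs(4, alex))
    gml = tmp_path / "fw.graphml"
    export_graph(fw, gml, "graphml")
    parsed = nx.read_graphml(gml)
    assert set(parsed.nodes) == set(fw.nodes)
    assert parsed.number_of_edges() == len(fw.edges)

    dot = tmp_path / "fw.dot"
    export_graph(fw, dot, "dot")
    text = dot.read_text()
    node_ids = [line.split()[0] for line in text.splitlines()
                if "category=" in line and "->" not in line]
    assert len(node_ids) == len(set(node_ids)) == len(fw.nodes)
    with pytest.raises(GraphError):
        export_graph(fw, tmp_path / "fw.xyz", "xyz")
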