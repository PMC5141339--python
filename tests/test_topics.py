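"""Co-occurrence networks and random-walk trap detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from narraframe.corpus import Corpus, segment_and_tag
from narraframe.topics import (
    CooccurrenceNetwork,
    TopicsError,
    build_cooccurrence_network,
    detect_traps,
)

from conftest import make_post


def _corpus(posts):
    return segment_and_tag(Corpus(posts=posts))


def test_cooccurrence_thread_counts():
    corpus = _corpus([
        make_post(post_id="p1", thread="t1",
                  text="The exemption reached the school."),
        make_post(post_id="p2", thread="t2",
                  text="Another exemption at another school."),
        make_post(post_id="p3", thread="t2", text="The school again."),
    ])
    net = build_cooccurrence_network(corpus)
    assert net.graph["exemption"]["school"]["weight"] == 2


def test_no_edge_without_cooccurrence():
    corpus = _corpus([
        make_post(post_id="p1", thread="t1", text="The exemption arrived."),
        make_post(post_id="p2", thread="t2", text="The school opened."),
    ])
    net = build_cooccurrence_network(corpus)
    assert not net.graph.has_edge("exemption", "school")


def test_empty_corpus_fatal():
    with pytest.raises(TopicsError):
        build_cooccurrence_network(Corpus())


def _modularity(graph, partition):
    """Newman modularity computed from first principles (the dwell-time
    objective of a stationary random walk, minus its null expectation)."""
    m2 = sum(d.get("weight", 1) for _, _, d in graph.edges(data=True)) * 2.0
    q = 0.0
    for part in partition:
        inside = sum(
            d.get("weight", 1)
            for u, v, d in graph.edges(data=True) if u in part and v in part
        ) * 2.0
        degree = sum(
            sum(d.get("weight", 1) for _, _, d in graph.edges(n, data=True))
            for n in part
        )
        q += inside / m2 - (degree / m2) ** 2
    return q


def _two_cliques():
    g = nx.Graph()
    for names in ("abcde", "vwxyz"):
        for i, u in enumerate(names):
            for v in names[i + 1:]:
                g.add_edge(u, v, weight=1)
    g.add_edge("a", "v", weight=1)
    return g


def test_two_cliques_split_matches_bruteforce_dwell_oracle():
    """Detected traps equal the best 2-partition found by enumerating all
    2-partitions and maximising the dwell objective directly."""
    g = _two_cliques()
    nodes = sorted(g.nodes)
    best_q, best_parts = -1.0, None
    for size in range(1, len(nodes) // 2 + 1):
        for left in itertools.combinations(nodes, size):
            parts = [set(left), set(nodes) - set(left)]
            q = _modularity(g, parts)
            if q > best_q:
                best_q, best_parts = q, parts
    root = detect_traps(CooccurrenceNetwork(g), max_depth=1, seed=0)
    detected = sorted(frozenset(c.words) for c in root.children)
    assert detected == sorted(frozenset(p) for p in best_parts)
    assert detected == [frozenset("abcde"), frozenset("vwxyz")]


def test_single_clique_one_trap_uniform_weights():
    g = nx.complete_graph(6)
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    root = detect_traps(CooccurrenceNetwork(g), seed=0)
    assert root.children == []
    assert len(root.words) == 6
    for p in root.words.values():
        assert p == pytest.approx(1 / 6, abs=1e-9)


def test_trap_weights_sum_to_one_and_hierarchy_is_tree():
    g = _two_cliques()
    root = detect_traps(CooccurrenceNetwork(g), max_depth=3, seed=0)
    seen = []
    for trap in root.walk():
        assert sum(trap.words.values()) == pytest.approx(1.0, abs=1e-9)
        seen.append(trap)
        for child in trap.children:
            assert child.parent is trap
            assert set(child.words) <= set(trap.words)
    # every trap reached exactly once => tree
    assert len(seen) == len({id(t) for t in seen})


def test_disconnected_components_processed_independently():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1)
    g.add_edge("x", "y", weight=1)
    root = detect_traps(CooccurrenceNetwork(g), seed=0)
    assert len(root.children) == 2
    assert sorted(sorted(c.words) for c in root.children) == [
        ["a", "b"], ["x", "y"],
    ]


@pytest.mark.parametrize("seed", range(10))
def test_planted_partition_block_recovery(seed):
    g = nx.Graph(nx.planted_partition_graph(2, 20, 0.3, 0.01, seed=seed))
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    root = detect_traps(CooccurrenceNetwork(g), max_depth=1, seed=seed)
    leaves = [t for t in root.walk() if not t.children] or [root]
    correct = 0
    for trap in leaves:
        blocks = [0 if node < 20 else 1 for node in trap.words]
        majority = max(set(blocks), key=blocks.count)
        correct += sum(1 for b in blocks if b == majority)
    assert correct / 40 >= 0.9


def test_planted_subvocabulary_recovered_as_trap():
    """A densely wired sub-vocabulary around the central topic word comes
    back as one trap with that word top-weighted."""
    vocab = ["exemption", "refusal", "belief", "requirements"]
    posts = []
    pid = 0
    # the topic threads wire the sub-vocabulary densely around "exemption"
    for other in vocab[1:]:
        for _ in range(4):
            pid += 1
            posts.append(make_post(
                post_id=f"p{pid}", thread=f"t{pid}",
                text=f"The exemption brings {other}."))
    # unrelated chatter forms a second community
    for pair in [("weather", "rain"), ("rain", "cloud"), ("weather", "cloud")]:
        for _ in range(4):
            pid += 1
            posts.append(make_post(
                post_id=f"p{pid}", thread=f"t{pid}",
                text=f"The {pair[0]} brings {pair[1]}."))
    corpus = _corpus(posts)
    net = build_cooccurrence_network(corpus)
    root = detect_traps(CooccurrenceNetwork(net.graph), max_depth=2, seed=0)
    traps = [t for t in root.walk() if not t.children] or [root]
    exemption_trap = next(t for t in traps if "exemption" in t.words)
    assert set(vocab) <= set(exemption_trap.words)
    assert exemption_trap.top_words(1)[0][0] == "exemption"
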