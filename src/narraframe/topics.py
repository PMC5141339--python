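"""CRWT-style topic discovery: co-occurrence network -> random-walk traps.

A co-occurrence network over content nouns (stopwords removed) is built
with edges weighted by the number of documents — threads by default — in
which two words co-occur.  The network is then decomposed into a
hierarchy of *topic traps*: regions where a random walk dwells, found by
recursive modularity-maximising community detection on the weighted graph
(modularity measures exactly the excess dwell probability of a stationary
random walk within parts).  Within each trap, words are weighted by their
PageRank on the trap's induced subgraph, so every trap's weights sum to 1.

This is a CRWT-style variant: the original trap-detection objective lives
in prior work and only the documented behaviour (co-occurrence network,
trap hierarchy, steady-state word weights) is implemented here.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from ._text import NOUN_TAGS
from .corpus import Corpus


class TopicsError(ValueError):
    pass


#: minimal English stopword list for content-word selection
STOPWORDS = frozenset(
    """a an the and or but if then than so because while about into over under
    again further once here there all any both each few more most other some
    such only own same too very can will just should now i me my we our you
    your he him his she her it its they them their what which who this that
    these those am is are was were be been being have has had do does did of
    at by for with to from in on as not no nor out up down off when where why
    how s t don ve ll re also get got one two like would could may might must
    something anything nothing thing things way lot bit im dont doesnt isnt
    didnt cant wont""".split()
)


@dataclass
class CooccurrenceNetwork:
    """Undirected word network; edge weight = co-document count."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class TopicTrap:
    """One node of the trap hierarchy.

    ``weights`` maps each word of the trap to its PageRank on the trap's
    induced subgraph (summing to 1 within the trap); children partition
    (a subset of) the parent's word set.
    """

    words: Dict[str, float]
    depth: int
    children: List["TopicTrap"] = field(default_factory=list)
    parent: Optional["TopicTrap"] = None

    def top_words(self, k: int = 10) -> List[Tuple[str, float]]:
        return sorted(self.words.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


def build_cooccurrence_network(
    corpus: Corpus,
    document_unit: str = "thread",
    min_weight: int = 1,
    stopwords: frozenset = STOPWORDS,
) -> CooccurrenceNetwork:
    """Noun co-occurrence network at thread (default) or sentence level.

    Edge (u, v) weight = number of documents containing both u and v;
    edges below ``min_weight`` are dropped.
    """
    if not corpus.posts:
        raise TopicsError("empty corpus")
    if not corpus.sentences:
        raise TopicsError("corpus must be segmented and tagged first")
    if document_unit not in ("thread", "sentence"):
        raise TopicsError(f"unknown document unit {document_unit!r}")

    thread_of = {p.post_id: p.thread_id for p in corpus.posts}
    documents: Dict[str, Set[str]] = {}
    for sentence in corpus.sentences:
        if document_unit == "thread":
            doc_id = thread_of[sentence.post_ref]
        else:
            doc_id = sentence.sent_id
        words = documents.setdefault(doc_id, set())
        for tok, tag in sentence.tokens:
            low = tok.lower()
            if tag in NOUN_TAGS and low not in stopwords and len(low) > 1:
                words.add(low)

    weights: Counter = Counter()
    for words in documents.values():
        for u, v in combinations(sorted(words), 2):
            weights[(u, v)] += 1
    graph = nx.Graph()
    for words in documents.values():
        graph.add_nodes_from(words)
    for (u, v), w in weights.items():
        if w >= min_weight:
            graph.add_edge(u, v, weight=w)
    return CooccurrenceNetwork(graph=graph)


def _pagerank_weights(graph: nx.Graph, damping: float, tol: float) -> Dict[str, float]:
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): 1.0}
    pr = nx.pagerank(graph, alpha=damping, tol=tol, max_iter=1000,
                     weight="weight")
    total = sum(pr.values())
    return {w: p / total for w, p in pr.items()}


def _detect_in_subgraph(
    graph: nx.Graph,
    depth: int,
    max_depth: int,
    size_floor: int,
    seed: int,
    damping: float,
    tol: float,
) -> TopicTrap:
    trap = TopicTrap(words=_pagerank_weights(graph, damping, tol), depth=depth)
    if depth >= max_depth or graph.number_of_nodes() < size_floor:
        return trap
    if graph.number_of_edges() == 0:
        return trap
    communities = nx.community.louvain_communities(
        graph, weight="weight", seed=seed
    )
    if len(communities) <= 1:
        return trap
    for community in sorted(communities, key=lambda c: sorted(c)[0]):
        sub = graph.subgraph(community).copy()
        child = _detect_in_subgraph(
            sub, depth + 1, max_depth, size_floor, seed, damping, tol
        )
        child.parent = trap
        trap.children.append(child)
    return trap


def detect_traps(
    net: CooccurrenceNetwork,
    max_depth: int = 3,
    size_floor: int = 4,
    seed: int = 0,
    damping: float = 0.85,
    tol: float = 1e-10,
) -> TopicTrap:
    """Decompose the network into a hierarchy of random-walk traps.

    Returns a synthetic root whose children are the traps; disconnected
    components are processed independently.  Recursion stops at
    ``max_depth``, below ``size_floor`` nodes, or when no partition
    improves modularity.  PageRank uses damping 0.85 and tolerance 1e-10
    by default.
    """
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise TopicsError("empty network")
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    if len(components) == 1:
        return _detect_in_subgraph(graph.copy(), 0, max_depth, size_floor,
                                   seed, damping, tol)
    # disconnected: synthetic root, one child trap per component
    pr = nx.pagerank(graph, alpha=damping, tol=tol, max_iter=1000,
                     weight="weight")
    total = sum(pr.values())
    root = TopicTrap(words={w: p / total for w, p in pr.items()}, depth=0)
    for component in components:
        sub = graph.subgraph(component).copy()
        child = _detect_in_subgraph(sub, 1, max_depth, size_floor, seed,
                                    damping, tol)
        child.parent = root
        root.children.append(child)
    return root


def trap_hierarchy_to_dict(trap: TopicTrap) -> dict:
    return {
        "depth": trap.depth,
        "words": {w: round(p, 10) for w, p in sorted(trap.words.items())},
        "children": [trap_hierarchy_to_dict(c) for c in trap.children],
    }


def export_traps_json(trap: TopicTrap, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(trap_hierarchy_to_dict(trap), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path
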