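"""Story graphs and the aggregate narrative framework.

A *story graph* renders one actant-pair context as a directed network:
actants are nodes, and each distinct (source, target, relationship
category) triple becomes an edge whose weight is the number of supporting
relation instances.  Merging the story graphs of all contexts — summing
weights and recording contributing contexts per edge — yields the
*narrative framework*, the latent story structure that individual posts
partially activate.  Edges may additionally carry a narrative-role
annotation (orientation / threat / strategy / resolution) supplied as
configuration, mirroring the interpretive alignment of relationships to
the four-part personal-experience-narrative scheme.

Weights are supporting-instance counts (KL scores stay available as edge
metadata upstream): counts are interpretable and conserve exactly under
aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .lexicons import ActantLexicon
from .relations import RelationInstance

NARRATIVE_ROLES = ("orientation", "threat", "strategy", "resolution")

EdgeKey = Tuple[str, str, str]  # (source, target, category)


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    category: str
    weight: int
    sentence_ids: Tuple[str, ...] = ()
    contexts: Tuple[str, ...] = ()
    role: Optional[str] = None

    @property
    def key(self) -> EdgeKey:
        return (self.source, self.target, self.category)


@dataclass
class StoryGraph:
    """Directed graph of one actant-pair context."""

    context_label: str
    nodes: Dict[str, str]  # actant -> category
    edges: Dict[EdgeKey, Edge] = field(default_factory=dict)

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges.values())


@dataclass
class NarrativeFramework:
    """Aggregate graph merged over all story graphs."""

    nodes: Dict[str, str]
    edges: Dict[EdgeKey, Edge] = field(default_factory=dict)

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges.values())


def build_story_graph(
    context_label: str,
    actant_pair: Tuple[str, str],
    relations: Sequence[RelationInstance],
    lex: ActantLexicon,
) -> StoryGraph:
    """Aggregate relation instances of one context into a story graph.

    Nodes are the context's pair plus every actant appearing in an
    instance; no relations yields the two pair nodes and zero edges.
    """
    nodes: Dict[str, str] = {}
    for actant in actant_pair:
        if actant not in lex:
            raise GraphError(f"actant {actant!r} absent from lexicon")
        nodes[actant] = lex.category_of(actant)
    grouped: Dict[EdgeKey, List[RelationInstance]] = {}
    for inst in relations:
        for actant in (inst.source, inst.target):
            if actant not in lex:
                raise GraphError(f"actant {actant!r} absent from lexicon")
            nodes[actant] = lex.category_of(actant)
        if inst.source == inst.target:
            raise GraphError("self-loop relation instance")
        grouped.setdefault((inst.source, inst.target, inst.category), []).append(inst)
    edges = {
        key: Edge(
            source=key[0], target=key[1], category=key[2],
            weight=len(insts),
            sentence_ids=tuple(sorted({i.sent_id for i in insts})),
            contexts=(context_label,),
        )
        for key, insts in grouped.items()
    }
    return StoryGraph(context_label=context_label, nodes=nodes, edges=edges)


def aggregate(graphs: Iterable[StoryGraph]) -> NarrativeFramework:
    """Merge story graphs into the narrative framework.

    Edges merge by (source, target, category); weights add exactly and
    contributing contexts are recorded, so context-dependent relationships
    between the same pair remain distinct edges.  Aggregation is
    order-invariant and associative.
    """
    nodes: Dict[str, str] = {}
    merged: Dict[EdgeKey, Edge] = {}
    for graph in graphs:
        nodes.update(graph.nodes)
        for key, edge in graph.edges.items():
            if key in merged:
                prior = merged[key]
                merged[key] = replace(
                    prior,
                    weight=prior.weight + edge.weight,
                    sentence_ids=tuple(sorted(set(prior.sentence_ids)
                                              | set(edge.sentence_ids))),
                    contexts=tuple(sorted(set(prior.contexts)
                                          | set(edge.contexts))),
                )
            else:
                merged[key] = edge
    return NarrativeFramework(nodes=dict(sorted(nodes.items())),
                              edges=dict(sorted(merged.items())))


def annotate_roles(
    fw: NarrativeFramework,
    role_map: Mapping[EdgeKey, str],
    categories: Optional[Sequence[str]] = None,
) -> NarrativeFramework:
    """Label framework edges with narrative roles from a configuration map.

    ``role_map`` maps (source, target, category) patterns to a role in
    ``orientation | threat | strategy | resolution``; unmatched edges stay
    unannotated.  Patterns naming an unknown category (against
    ``categories`` when supplied) or role are configuration errors.
    """
    for (src, tgt, cat), role in role_map.items():
        if role not in NARRATIVE_ROLES:
            raise GraphError(f"unknown narrative role {role!r}")
        if categories is not None and cat not in categories:
            raise GraphError(f"role map references unknown category {cat!r}")
    edges = {
        key: (replace(edge, role=role_map[key]) if key in role_map else edge)
        for key, edge in fw.edges.items()
    }
    return NarrativeFramework(nodes=dict(fw.nodes), edges=edges)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _as_dict(g: StoryGraph | NarrativeFramework) -> dict:
    payload = {
        "nodes": [
            {"name": name, "category": cat} for name, cat in sorted(g.nodes.items())
        ],
        "edges": [
            {
                "source": e.source, "target": e.target, "category": e.category,
                "weight": e.weight,
                "sentence_ids": list(e.sentence_ids),
                "contexts": list(e.contexts),
                "role": e.role,
            }
            for _, e in sorted(g.edges.items())
        ],
    }
    if isinstance(g, StoryGraph):
        payload["context_label"] = g.context_label
    return payload


def to_networkx(g: StoryGraph | NarrativeFramework) -> nx.MultiDiGraph:
    out = nx.MultiDiGraph()
    for name, cat in g.nodes.items():
        out.add_node(name, category=cat)
    for e in g.edges.values():
        out.add_edge(
            e.source, e.target, key=e.category, category=e.category,
            weight=e.weight, contexts="|".join(e.contexts),
            sentence_ids="|".join(e.sentence_ids), role=e.role or "",
        )
    return out


def export_graph(
    g: StoryGraph | NarrativeFramework, path: str | Path, format: str
) -> Path:
    """Write a graph losslessly as ``graphml``, ``dot`` or ``json``."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_as_dict(g), indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(to_networkx(g), path)
    elif format == "dot":
        lines = ["digraph narrative {"]
        ids = {name: f"n{i}" for i, name in enumerate(sorted(g.nodes))}
        for name in sorted(g.nodes):
            lines.append(
                f'  {ids[name]} [label="{name}" category="{g.nodes[name]}"];'
            )
        for _, e in sorted(g.edges.items()):
            attrs = f'label="{e.category}" weight={e.weight}'
            if e.role:
                attrs += f' role="{e.role}"'
            lines.append(f"  {ids[e.source]} -> {ids[e.target]} [{attrs}];")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise GraphError(f"unknown export format {format!r}")
    return path


def import_graph_json(path: str | Path) -> NarrativeFramework:
    """Inverse of the JSON export (story graphs re-import as frameworks
    when the context label is absent)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    nodes = {n["name"]: n["category"] for n in data["nodes"]}
    edges = {}
    for e in data["edges"]:
        edge = Edge(
            source=e["source"], target=e["target"], category=e["category"],
            weight=e["weight"], sentence_ids=tuple(e["sentence_ids"]),
            contexts=tuple(e["contexts"]), role=e.get("role"),
        )
        edges[edge.key] = edge
    if "context_label" in data:
        sg = StoryGraph(context_label=data["context_label"], nodes=nodes,
                        edges=edges)
        return sg  # type: ignore[return-value]
    return NarrativeFramework(nodes=nodes, edges=edges)
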