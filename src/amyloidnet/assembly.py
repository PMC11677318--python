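"""Merge the four edge sets into one heterogeneous simple undirected graph.

The network is a :class:`networkx.Graph` whose nodes carry ``category``
(disease / protein / drug), ``protein_roles`` (frozenset) and
``display_name`` attributes, and whose edges carry ``edge_type`` and,
for protein-protein interactions, the combined confidence ``score``.
Because the three id namespaces are disjoint, one edge per unordered
pair is also one edge per (pair, edge_type).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ConsistencyError
from .records import (
    DISEASE,
    DRUG,
    DRUG_TARGET,
    EDGE_ENDPOINT_CATEGORIES,
    INTERACTOR,
    PROTEIN,
    PROTEIN_DRUG,
    PROTEIN_PROTEIN,
    AssociationEdge,
    NodeRecord,
    ScoredPPIEdge,
)


def build_network(
    dp: list[AssociationEdge],
    pp: list[ScoredPPIEdge],
    pd_edges: list[AssociationEdge],
    dd: list[AssociationEdge],
    node_records: dict[str, NodeRecord] | None = None,
) -> nx.Graph:
    """Assemble the heterogeneous network from the four filtered edge lists.

    Nodes are created on first sight with the category implied by the
    edge-type slot; an id later seen under a different category is a
    hard :class:`ConsistencyError` (namespaces must never collide).
    Proteins seen only in PPI edges are tagged ``interactor``; every
    drug-targeted protein additionally gains ``drug_target``.
    """
    g = nx.Graph()

    def ensure(nid: str, category: str) -> None:
        if nid in g:
            seen = g.nodes[nid]["category"]
            if seen != category:
                raise ConsistencyError(
                    f"node {nid!r} used as both {seen} and {category}"
                )
        else:
            g.add_node(nid, category=category, protein_roles=frozenset(),
                       display_name=nid)

    for e in dp:
        ensure(e.source, DISEASE)
        ensure(e.target, PROTEIN)
        g.add_edge(e.source, e.target, edge_type=e.edge_type)
        if e.protein_role_at_assoc:
            roles = g.nodes[e.target]["protein_roles"] | e.protein_role_at_assoc
            g.nodes[e.target]["protein_roles"] = roles
    for pe in pp:
        ensure(pe.protein_a, PROTEIN)
        ensure(pe.protein_b, PROTEIN)
        g.add_edge(pe.protein_a, pe.protein_b, edge_type=PROTEIN_PROTEIN,
                   score=pe.combined_score)
    for e in pd_edges:
        src_cat, tgt_cat = EDGE_ENDPOINT_CATEGORIES[e.edge_type]
        ensure(e.source, src_cat)
        ensure(e.target, tgt_cat)
        g.add_edge(e.source, e.target, edge_type=e.edge_type)
    for e in dd:
        ensure(e.source, DISEASE)
        ensure(e.target, DRUG)
        g.add_edge(e.source, e.target, edge_type=e.edge_type)

    # role tagging from context
    for nid, data in g.nodes(data=True):
        if data["category"] != PROTEIN:
            continue
        roles = set(data["protein_roles"])
        types = {g.edges[nid, nb]["edge_type"] for nb in g.neighbors(nid)}
        if PROTEIN_DRUG in types:
            roles.add(DRUG_TARGET)
        if PROTEIN_PROTEIN in types and not (roles - {DRUG_TARGET}):
            roles.add(INTERACTOR)
        data["protein_roles"] = frozenset(roles)

    if node_records:
        for nid, rec in node_records.items():
            if nid not in g:
                continue
            if g.nodes[nid]["category"] != rec.category:
                raise ConsistencyError(
                    f"node {nid!r}: record category {rec.category} clashes "
                    f"with inferred {g.nodes[nid]['category']}"
                )
            if rec.display_name:
                g.nodes[nid]["display_name"] = rec.display_name
            if rec.category == PROTEIN and rec.protein_roles:
                g.nodes[nid]["protein_roles"] = (
                    g.nodes[nid]["protein_roles"] | rec.protein_roles
                )
    return g


def nodes_of_category(net: nx.Graph, category: str) -> list[str]:
    return [n for n, c in net.nodes(data="category") if c == category]


@dataclass
class ComponentReport:
    """Connected-component census of a heterogeneous network."""

    component_count: int
    component_sizes: list[int]
    isolated_disease_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def connected_components(net: nx.Graph) -> ComponentReport:
    """Component sizes (descending) plus every disease outside the
    largest component — diseases whose proteins connect to nothing else
    remain unconnected islands."""
    comps = sorted(nx.connected_components(net), key=len, reverse=True)
    if not comps:
        return ComponentReport(0, [])
    largest = comps[0]
    isolated = sorted(
        n for n, c in net.nodes(data="category")
        if c == DISEASE and n not in largest
    )
    return ComponentReport(len(comps), [len(c) for c in comps], isolated)


# ---------------------------------------------------------------------------
# writers


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export for Cytoscape interop (frozensets joined with commas)."""
    g = net.copy()
    for _, data in g.nodes(data=True):
        roles = data.pop("protein_roles", frozenset())
        data["protein_roles"] = ",".join(sorted(roles))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_graphml`, restoring role sets."""
    g = nx.read_graphml(path)
    for _, data in g.nodes(data=True):
        raw = data.get("protein_roles", "")
        data["protein_roles"] = frozenset(r for r in raw.split(",") if r)
    return g


def write_edgelist_tsv(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tedge_type\tscore\n")
        for a, b, data in sorted(net.edges(data=True)):
            score = data.get("score")
            fh.write(f"{a}\t{b}\t{data.get('edge_type', '')}\t"
                     f"{'' if score is None else f'{score:.3f}'}\n")
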