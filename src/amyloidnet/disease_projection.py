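"""Weighted disease-disease projection by shared first neighbors.

Each disease's first-neighbor set (the proteins and drugs directly
linked to it) is intersected pairwise; the intersection sizes form a
symmetric count matrix, which becomes a weighted disease network after
dropping zero-weight pairs.  Densely connected disease groups are the
maximal cliques of that network, ranked by their internal weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConsistencyError, ValidationError
from .records import DISEASE, DRUG, PROTEIN


@dataclass(frozen=True)
class DiseaseSubnetwork:
    """A disease and its first neighbors (proteins and drugs only)."""

    disease_id: str
    neighbor_ids: frozenset[str]


def first_neighbor_subnetwork(net: nx.Graph, disease_id: str) -> DiseaseSubnetwork:
    """Isolate the first neighbors of one disease.

    Diseases connect only through protein/drug intermediates in this
    scheme, so any disease nodes adjacent by construction are excluded.
    """
    if disease_id not in net:
        raise ValidationError(f"unknown node {disease_id!r}")
    if net.nodes[disease_id].get("category") != DISEASE:
        raise ValidationError(f"{disease_id!r} is not a disease node")
    nbrs = frozenset(
        n for n in net.neighbors(disease_id)
        if net.nodes[n].get("category") != DISEASE
    )
    return DiseaseSubnetwork(disease_id, nbrs)


@dataclass
class CommonNeighborMatrix:
    """Symmetric matrix of shared-first-neighbor counts between diseases.

    The diagonal is masked (kept at 0) so it can never leak into the
    projected network as a self-edge.
    """

    disease_ids: list[str]
    counts: np.ndarray

    def entry(self, a: str, b: str) -> int:
        i, j = self.disease_ids.index(a), self.disease_ids.index(b)
        return int(self.counts[i, j])

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("disease_id\t" + "\t".join(self.disease_ids) + "\n")
            for did, row in zip(self.disease_ids, self.counts):
                fh.write(did + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def common_neighbor_matrix(
    net: nx.Graph, disease_ids: list[str] | None = None,
) -> CommonNeighborMatrix:
    """w_ij = |N(i) ∩ N(j)| over protein/drug neighbors."""
    if disease_ids is None:
        disease_ids = sorted(
            n for n, c in net.nodes(data="category") if c == DISEASE
        )
    if len(disease_ids) < 2:
        raise ValidationError("need at least 2 diseases")
    subs = [first_neighbor_subnetwork(net, d).neighbor_ids for d in disease_ids]
    k = len(disease_ids)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            w = len(subs[i] & subs[j])
            counts[i, j] = counts[j, i] = w
    return CommonNeighborMatrix(list(disease_ids), counts)


def build_disease_network(matrix: CommonNeighborMatrix) -> nx.Graph:
    """Weighted disease network; zero-weight pairs carry no edge, but
    every disease remains as a node (isolated singletons permitted)."""
    if not np.array_equal(matrix.counts, matrix.counts.T):
        raise ConsistencyError("common-neighbor matrix is not symmetric")
    g = nx.Graph()
    g.add_nodes_from(matrix.disease_ids)
    k = len(matrix.disease_ids)
    for i in range(k):
        for j in range(i + 1, k):
            w = int(matrix.counts[i, j])
            if w > 0:
                g.add_edge(matrix.disease_ids[i], matrix.disease_ids[j],
                           weight=w)
    return g


@dataclass
class DiseaseGroup:
    """A clique of diseases in the weighted disease network."""

    member_ids: tuple[str, ...]
    min_internal_weight: int
    total_internal_weight: int
    internal_weights: dict[str, int] = field(default_factory=dict)
    shared_neighbors: "SharedNeighborReport | None" = None


def find_dense_groups(
    disease_net: nx.Graph, min_size: int = 3, hetero_net: nx.Graph | None = None,
) -> list[DiseaseGroup]:
    """All maximal cliques of size >= min_size, ranked by
    (min internal weight desc, total internal weight desc, members).

    If the parent heterogeneous network is supplied, each group is
    annotated with its categorised shared-neighbor report.
    """
    groups = []
    for clique in nx.find_cliques(disease_net):
        if len(clique) < min_size:
            continue
        members = tuple(sorted(clique))
        weights = {}
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                weights[f"{a}|{b}"] = int(disease_net.edges[a, b]["weight"])
        group = DiseaseGroup(
            member_ids=members,
            min_internal_weight=min(weights.values()),
            total_internal_weight=sum(weights.values()),
            internal_weights=weights,
        )
        if hetero_net is not None:
            group.shared_neighbors = shared_neighbor_report(hetero_net, members)
        groups.append(group)
    groups.sort(key=lambda g: (-g.min_internal_weight,
                               -g.total_internal_weight, g.member_ids))
    return groups


@dataclass
class SharedNeighborReport:
    """Common neighbors of a disease group, partitioned by category/role."""

    drugs: list[str]
    proteins_by_role: dict[str, list[str]]
    n_drugs: int
    n_proteins: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def shared_neighbor_report(net: nx.Graph, member_ids) -> SharedNeighborReport:
    """Intersect all members' first-neighbor sets and categorise the result."""
    members = list(member_ids)
    if not members:
        raise ValidationError("empty disease group")
    common: frozenset[str] | None = None
    for d in members:
        nbrs = first_neighbor_subnetwork(net, d).neighbor_ids
        common = nbrs if common is None else (common & nbrs)
    drugs = sorted(n for n in common if net.nodes[n]["category"] == DRUG)
    proteins = sorted(n for n in common if net.nodes[n]["category"] == PROTEIN)
    by_role: dict[str, list[str]] = {}
    for p in proteins:
        roles = net.nodes[p].get("protein_roles") or frozenset({"untagged"})
        for role in sorted(roles):
            by_role.setdefault(role, []).append(p)
    return SharedNeighborReport(
        drugs=drugs, proteins_by_role=by_role,
        n_drugs=len(drugs), n_proteins=len(proteins),
    )
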