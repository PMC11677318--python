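"""Betweenness-based drug-repurposing candidate ranking.

A drug qualifies as a candidate when (a) it targets at least one
amyloidogenic protein, (b) at least one disease associated with such a
target has no existing indication edge to the drug, and (c) it is not on
a user-supplied exclusion list (the machine-checkable stand-in for a
manual literature screen).  Candidates are then ranked by exact Brandes
betweenness centrality on the full heterogeneous network — a drug
bridging otherwise-distant regions of the network is the interesting
repurposing prospect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import networkx as nx

from .errors import ConsistencyError, ValidationError
from .records import (
    AMYLOIDOGENIC,
    DISEASE,
    DISEASE_DRUG,
    DISEASE_PROTEIN,
    DRUG,
    PROTEIN_DRUG,
    PROTEIN_PROTEIN,
    ScoredPPIEdge,
)

MEDIUM_SCORE_RANGE = (0.700, 0.900)


def betweenness(net: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Exact shortest-path betweenness, all edge types unweighted.

    With fewer than 3 nodes the normalisation divisor vanishes; by
    convention every node then scores 0.
    """
    if normalized and net.number_of_nodes() < 3:
        return {n: 0.0 for n in net}
    return nx.betweenness_centrality(net, normalized=normalized)


@dataclass
class RepurposingCandidate:
    """A drug with amyloidogenic targets and unexploited diseases."""

    drug_id: str
    amyloidogenic_targets: list[str]
    candidate_diseases: list[str]
    betweenness: float | None = None
    rank: int | None = None
    excluded_by_list: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def candidate_filter(
    net: nx.Graph, exclusion_list=(),
) -> list[RepurposingCandidate]:
    """Apply the amyloidogenic-target and no-existing-indication filters.

    Drugs on the exclusion list that otherwise qualify are returned with
    ``excluded_by_list=True`` so the pass/fail record stays auditable;
    they are skipped by :func:`rank_candidates`.
    """
    excluded = set(exclusion_list)
    out = []
    for drug, cat in net.nodes(data="category"):
        if cat != DRUG:
            continue
        targets = sorted(
            p for p in net.neighbors(drug)
            if net.edges[drug, p].get("edge_type") == PROTEIN_DRUG
            and AMYLOIDOGENIC in net.nodes[p].get("protein_roles", frozenset())
        )
        if not targets:
            continue
        diseases = set()
        for p in targets:
            for d in net.neighbors(p):
                if (net.nodes[d].get("category") == DISEASE
                        and net.edges[p, d].get("edge_type") == DISEASE_PROTEIN):
                    diseases.add(d)
        candidate_diseases = sorted(
            d for d in diseases
            if not (net.has_edge(d, drug)
                    and net.edges[d, drug].get("edge_type") == DISEASE_DRUG)
        )
        if not candidate_diseases:
            continue
        out.append(RepurposingCandidate(
            drug_id=drug,
            amyloidogenic_targets=targets,
            candidate_diseases=candidate_diseases,
            excluded_by_list=drug in excluded,
        ))
    out.sort(key=lambda c: c.drug_id)
    return out


def rank_candidates(
    candidates: list[RepurposingCandidate],
    centrality: dict[str, float],
) -> list[RepurposingCandidate]:
    """Order non-excluded candidates by betweenness descending,
    lexicographic drug id on ties; ranks start at 1."""
    ranked = []
    for c in candidates:
        if c.excluded_by_list:
            continue
        if c.drug_id not in centrality:
            raise ConsistencyError(
                f"candidate {c.drug_id} missing from centrality table"
            )
        ranked.append(RepurposingCandidate(
            drug_id=c.drug_id,
            amyloidogenic_targets=list(c.amyloidogenic_targets),
            candidate_diseases=list(c.candidate_diseases),
            betweenness=centrality[c.drug_id],
        ))
    ranked.sort(key=lambda c: (-c.betweenness, c.drug_id))
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def context_subnetwork(
    net: nx.Graph, drug_id: str,
    medium_ppi: list[ScoredPPIEdge] | None = None,
) -> nx.Graph:
    """Two-hop neighborhood of a drug, optionally layered with
    medium-confidence PPIs.

    Medium edges (scores in [0.700, 0.900)) extend the visible context —
    they participate in the 2-hop reach and are tier-tagged ``medium`` —
    but they are a display layer only and never enter centrality or
    projection computations on the main network.
    """
    if drug_id not in net:
        raise ValidationError(f"unknown drug {drug_id!r}")
    aug = net.copy()
    medium_pairs = set()
    for e in medium_ppi or ():
        lo, hi = MEDIUM_SCORE_RANGE
        if not (lo <= e.combined_score < hi):
            raise ValidationError(
                f"medium edge {e.pair} score {e.combined_score} outside "
                f"[{lo}, {hi})"
            )
        if not aug.has_edge(*e.pair):
            aug.add_edge(*e.pair, edge_type=PROTEIN_PROTEIN,
                         score=e.combined_score)
            medium_pairs.add(e.pair)
    ctx = nx.ego_graph(aug, drug_id, radius=2).copy()
    for a, b, data in ctx.edges(data=True):
        pair = (a, b) if a < b else (b, a)
        data["tier"] = "medium" if pair in medium_pairs else "high"
    ctx.graph["center"] = drug_id
    return ctx


def candidates_to_json(candidates: list[RepurposingCandidate]) -> str:
    return json.dumps([c.to_dict() for c in candidates], indent=2)
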