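"""Typed records for the heterogeneous disease-protein-drug network.

Node identifiers live in three disjoint namespaces: free-text disease
slugs, UniProt accessions for proteins, and DrugBank accessions
(``DB`` + 5 digits) for drugs.  A protein may hold several roles at once
(e.g. amyloidogenic *and* drug target), so roles are a frozenset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DISEASE = "disease"
PROTEIN = "protein"
DRUG = "drug"
CATEGORIES = (DISEASE, PROTEIN, DRUG)

# protein roles
AMYLOIDOGENIC = "amyloidogenic"
CO_DEPOSITED = "co_deposited"
INTERACTOR = "interactor"
DRUG_TARGET = "drug_target"
PROTEIN_ROLES = (AMYLOIDOGENIC, CO_DEPOSITED, INTERACTOR, DRUG_TARGET)
ASSOCIATION_ROLES = (AMYLOIDOGENIC, CO_DEPOSITED)

# edge types
DISEASE_PROTEIN = "disease-protein"
PROTEIN_PROTEIN = "protein-protein"
PROTEIN_DRUG = "protein-drug"
DISEASE_DRUG = "disease-drug"
EDGE_TYPES = (DISEASE_PROTEIN, PROTEIN_PROTEIN, PROTEIN_DRUG, DISEASE_DRUG)

#: endpoint categories implied by each edge type, in (source, target) order
EDGE_ENDPOINT_CATEGORIES = {
    DISEASE_PROTEIN: (DISEASE, PROTEIN),
    PROTEIN_PROTEIN: (PROTEIN, PROTEIN),
    PROTEIN_DRUG: (PROTEIN, DRUG),
    DISEASE_DRUG: (DISEASE, DRUG),
}

DRUGBANK_ID_RE = re.compile(r"^DB\d{5}$")


@dataclass(frozen=True)
class NodeRecord:
    """One node of the heterogeneous network."""

    id: str
    category: str
    protein_roles: frozenset[str] = field(default_factory=frozenset)
    display_name: str = ""
    organism_tag: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.protein_roles and self.category != PROTEIN:
            raise ValueError("protein_roles only allowed for proteins")

    def with_roles(self, roles: frozenset[str]) -> "NodeRecord":
        return NodeRecord(
            self.id, self.category, self.protein_roles | roles,
            self.display_name, self.organism_tag,
        )


@dataclass(frozen=True)
class ScoredPPIEdge:
    """Confidence-scored protein-protein interaction.

    The unordered pair is the identity: endpoints are stored in
    lexicographic order so that (a, b) and (b, a) compare equal.
    """

    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction {self.protein_a}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"score {self.combined_score} outside [0, 1]")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class AssociationEdge:
    """A typed association between two heterogeneous nodes.

    ``protein_role_at_assoc`` carries the deposition role(s) a protein has
    in a specific disease; the same protein may be amyloidogenic in one
    disease and co-deposited in another, so the per-edge tag is a set.
    """

    source: str
    target: str
    edge_type: str
    protein_role_at_assoc: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)
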