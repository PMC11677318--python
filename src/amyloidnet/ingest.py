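"""Readers and filters for the four association datasets.

Every reader accepts plain tab-delimited text (header row required,
``#`` comment lines ignored); disease-protein associations are also
accepted as a minimal XML dialect mirroring how amyloidosis registries
ship disease entries with protein children.

The protein-protein table is filtered the way a practitioner pulls a
high-confidence physical subnetwork from STRING: scores normalised to
[0, 1] (auto-detecting the 0-1000 integer dialect), non-human rows
dropped, a confidence floor applied (default 0.900, inclusive), pairs
de-duplicated keeping the maximum score, and each protein limited to its
``max_neighbors`` best partners.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .records import (
    ASSOCIATION_ROLES,
    DISEASE,
    DISEASE_DRUG,
    DISEASE_PROTEIN,
    DRUG,
    DRUGBANK_ID_RE,
    PROTEIN,
    PROTEIN_DRUG,
    AssociationEdge,
    NodeRecord,
    ScoredPPIEdge,
)

logger = logging.getLogger(__name__)

HUMAN_TAG = "9606"

#: substances interacting non-specifically with many proteins, excluded by
#: default: zinc, copper, aluminium (DrugBank accessions)
DEFAULT_EXCLUDED_DRUGS = frozenset({"DB01593", "DB09130", "DB01370"})


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# disease-protein associations


def read_disease_protein_associations(
    path: str | Path, dialect: str = "tsv", stats: dict | None = None,
) -> tuple[list[AssociationEdge], dict[str, NodeRecord]]:
    """Parse disease-protein association records.

    Returns one edge per unique (disease, protein) pair — duplicate rows
    collapsed, per-edge role tags unioned — together with the node
    records seen, where a protein's role set is the union over all its
    diseases.
    """
    if dialect == "tsv":
        rows = _dp_rows_from_tsv(path)
    elif dialect == "xml":
        rows = _dp_rows_from_xml(path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    per_pair: dict[tuple[str, str], set[str]] = {}
    disease_names: dict[str, str] = {}
    for disease_id, disease_name, ac, role in rows:
        if role not in ASSOCIATION_ROLES:
            raise ValidationError(
                f"{path}: unknown role {role!r} for ({disease_id}, {ac})"
            )
        per_pair.setdefault((disease_id, ac), set()).add(role)
        disease_names.setdefault(disease_id, disease_name)

    edges = [
        AssociationEdge(d, p, DISEASE_PROTEIN, frozenset(roles))
        for (d, p), roles in sorted(per_pair.items())
    ]
    if stats is not None:
        stats.update(records_in=len(rows),
                     dropped_duplicate=len(rows) - len(per_pair),
                     records_out=len(edges))
    nodes: dict[str, NodeRecord] = {}
    for d, name in sorted(disease_names.items()):
        nodes[d] = NodeRecord(d, DISEASE, display_name=name or d)
    protein_roles: dict[str, set[str]] = {}
    for (_, p), roles in per_pair.items():
        protein_roles.setdefault(p, set()).update(roles)
    for p, roles in sorted(protein_roles.items()):
        nodes[p] = NodeRecord(p, PROTEIN, frozenset(roles), display_name=p,
                              organism_tag=HUMAN_TAG)
    return edges, nodes


def _dp_rows_from_tsv(path):
    df = _read_tsv(path, ["disease_id", "uniprot_ac", "role"])
    return [
        (str(r.disease_id), str(r.disease_id), str(r.uniprot_ac), str(r.role))
        for r in df.itertuples(index=False)
    ]


def _dp_rows_from_xml(path):
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: malformed XML at line {exc.position[0]}, "
                         f"column {exc.position[1]}: {exc.msg}") from exc
    rows = []
    for dis in tree.getroot().iter("disease"):
        did = dis.get("id")
        if did is None:
            raise ParseError(f"{path}: <disease> element missing 'id' attribute")
        name = dis.get("name", did)
        for prot in dis.iter("protein"):
            ac = prot.get("ac")
            role = prot.get("role")
            if ac is None or role is None:
                raise ParseError(
                    f"{path}: <protein> under disease {did!r} missing "
                    "'ac' or 'role' attribute"
                )
            rows.append((did, name, ac, role))
    return rows


# ---------------------------------------------------------------------------
# protein-protein interactions


def read_ppi_table(
    path: str | Path,
    min_score: float = 0.900,
    max_neighbors: int = 100,
    human_only: bool = True,
    human_tag: str = HUMAN_TAG,
    stats: dict | None = None,
) -> list[ScoredPPIEdge]:
    """Read and filter a scored PPI table.

    Filter chain: validate -> scale-normalise -> drop self-pairs ->
    human filter -> score floor (inclusive) -> de-duplicate keeping the
    max score -> neighbor cap -> canonical sort.  ``stats``, if given,
    is filled with records-in / dropped-per-rule / records-out counts.
    """
    df = _read_tsv(path, ["protein_a", "protein_b", "combined_score",
                          "organism_tag"])
    n_in = len(df)
    score = pd.to_numeric(df["combined_score"], errors="coerce")
    if score.isna().any():
        bad = df.loc[score.isna()].index[0]
        raise ValidationError(f"{path}: non-numeric combined_score in row {bad}")
    if ((score < 0) | (score > 1000)).any():
        raise ValidationError(f"{path}: combined_score outside [0, 1000]")
    if (score > 1).any():  # 0-1000 integer dialect
        score = score / 1000.0
    df = df.assign(combined_score=score)

    n0 = len(df)
    df = df[df["protein_a"] != df["protein_b"]]
    dropped_self = n0 - len(df)

    dropped_nonhuman = 0
    if human_only:
        n0 = len(df)
        df = df[df["organism_tag"].astype(str) == human_tag]
        dropped_nonhuman = n0 - len(df)

    n0 = len(df)
    df = df[df["combined_score"] >= min_score]
    dropped_score = n0 - len(df)

    best: dict[tuple[str, str], float] = {}
    for a, b, s in zip(df["protein_a"], df["protein_b"], df["combined_score"]):
        pair = (a, b) if a < b else (b, a)
        if s > best.get(pair, -1.0):
            best[pair] = s
    dropped_dup = len(df) - len(best)

    kept_pairs = _cap_neighbors(best, max_neighbors)
    dropped_cap = len(best) - len(kept_pairs)

    edges = [ScoredPPIEdge(a, b, best[(a, b)]) for a, b in sorted(kept_pairs)]
    if stats is not None:
        stats.update(
            records_in=n_in,
            dropped_self=dropped_self,
            dropped_nonhuman=dropped_nonhuman,
            dropped_below_min_score=dropped_score,
            dropped_duplicate=dropped_dup,
            dropped_neighbor_cap=dropped_cap,
            records_out=len(edges),
        )
    return edges


def _cap_neighbors(
    best: dict[tuple[str, str], float], max_neighbors: int,
) -> set[tuple[str, str]]:
    """Keep an edge iff each endpoint ranks the other in its top-N partners.

    Partners are ranked by score descending, lexicographic id on ties, so
    the cap is deterministic.
    """
    partners: dict[str, list[tuple[float, str]]] = {}
    for (a, b), s in best.items():
        partners.setdefault(a, []).append((s, b))
        partners.setdefault(b, []).append((s, a))
    allowed: dict[str, set[str]] = {}
    for node, plist in partners.items():
        plist.sort(key=lambda t: (-t[0], t[1]))
        allowed[node] = {p for _, p in plist[:max_neighbors]}
    return {
        (a, b) for (a, b) in best
        if b in allowed[a] and a in allowed[b]
    }


def dedupe_ppi(edges: list[ScoredPPIEdge]) -> list[ScoredPPIEdge]:
    """Collapse to unordered-pair uniqueness, keeping the maximum score.

    Output is canonically sorted by endpoint pair, so the function is a
    projection: applying it twice equals applying it once.
    """
    best: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.combined_score > best.get(e.pair, -1.0):
            best[e.pair] = e.combined_score
    return [ScoredPPIEdge(a, b, s) for (a, b), s in sorted(best.items())]


# ---------------------------------------------------------------------------
# drug tables


def read_drug_tables(
    targets_path: str | Path,
    indications_path: str | Path,
    excluded_drugs: frozenset[str] | set[str] = DEFAULT_EXCLUDED_DRUGS,
    stats: dict | None = None,
) -> tuple[list[AssociationEdge], list[AssociationEdge]]:
    """Read drug-target and drug-indication tables.

    Returns (protein-drug edges, disease-drug edges).  Rows touching an
    excluded drug id (by default the non-specific metal binders zinc,
    copper and aluminium) are dropped; duplicates collapsed; ids that do
    not look like DrugBank accessions are kept but logged.
    """
    excluded = frozenset(excluded_drugs)

    tdf = _read_tsv(targets_path, ["drugbank_id", "uniprot_ac"])
    idf = _read_tsv(indications_path, ["drugbank_id", "disease_id"])

    def process(df, other_col, edge_type):
        n_in = len(df)
        for did in df["drugbank_id"].unique():
            if not DRUGBANK_ID_RE.match(str(did)):
                logger.warning("drug id %r does not match DBnnnnn pattern "
                               "(row kept)", did)
        keep = ~df["drugbank_id"].isin(excluded)
        dropped_excluded = int((~keep).sum())
        df = df[keep]
        pairs = {(str(d), str(o))
                 for d, o in zip(df["drugbank_id"], df[other_col])}
        dropped_dup = len(df) - len(pairs)
        # edges run (protein|disease) -> drug
        edges = [AssociationEdge(o, d, edge_type) for d, o in sorted(pairs)]
        edges.sort(key=lambda e: e.pair)
        return edges, n_in, dropped_excluded, dropped_dup

    pd_edges, t_in, t_excl, t_dup = process(tdf, "uniprot_ac", PROTEIN_DRUG)
    dd_edges, i_in, i_excl, i_dup = process(idf, "disease_id", DISEASE_DRUG)
    if stats is not None:
        stats.update(
            targets_in=t_in, targets_dropped_excluded=t_excl,
            targets_dropped_duplicate=t_dup, targets_out=len(pd_edges),
            indications_in=i_in, indications_dropped_excluded=i_excl,
            indications_dropped_duplicate=i_dup, indications_out=len(dd_edges),
        )
    return pd_edges, dd_edges
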