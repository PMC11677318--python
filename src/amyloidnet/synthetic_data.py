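"""Synthetic fixture generator with known ground truth.

Emulates the statistical shape of an amyloidosis disease-protein-drug
dataset at roughly one quarter scale — tens of diseases, a couple
hundred proteins, a few hundred drugs — with:

* a heavy-tailed interactor degree distribution (discrete power law,
  wired configuration-model style with stub matching);
* PPI confidence scores spanning the 0.150-0.999 range, with the kept
  mass above the 0.900 high-confidence floor;
* sub-threshold, non-human, metal and duplicate rows planted to
  exercise every ingest filter;
* disease groups wired with exactly known shared-neighbor counts
  (a heavy triangle and a six-member clique by default, mirroring the
  structures such analyses surface);
* one bridging drug wired as the sole connector between a protein
  module and the rest of the network, guaranteeing it tops the
  betweenness ranking among drugs;
* isolated disease/protein islands that stay out of the giant component.

Identical (config, seed) produces byte-identical files, so fixtures are
never stored — they are regenerated on demand.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import InfeasibleError
from .records import AMYLOIDOGENIC, CO_DEPOSITED

METAL_DRUG_IDS = ("DB01593", "DB09130", "DB01370")  # zinc, copper, aluminium

#: protein module sizes around the planted bridging drug
_MODULE_A_INTERACTORS = 5
_MODULE_B_INTERACTORS = 7


@dataclass(frozen=True)
class PlantedGroup:
    """A disease clique wired to share exactly the stated neighbors."""

    members: tuple[int, ...]
    shared_drugs: int
    shared_proteins: int

    @property
    def pair_weight(self) -> int:
        return self.shared_drugs + self.shared_proteins


@dataclass(frozen=True)
class PlantedCandidate:
    """The bridging repurposing drug: its drug-pool index, the index of
    its amyloidogenic target in the background pool, and the number of
    protein targets (1 in module A + bridge_degree-1 in module B)."""

    drug_index: int = 0
    protein_index: int = 0
    bridge_degree: int = 2


@dataclass(frozen=True)
class NoiseCounts:
    """Planted filter-violating rows, per ingest rule."""

    subthreshold: int = 40
    nonhuman: int = 15
    metal: int = 6
    duplicate_ppi: int = 10
    duplicate_dp: int = 5
    duplicate_target: int = 5
    duplicate_indication: int = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset (seed mandatory)."""

    seed: int
    n_diseases: int = 19
    n_amyloidogenic: int = 24
    n_codeposited: int = 12
    n_interactors: int = 160
    n_drugs: int = 350
    ppi_score_range: tuple[float, float] = (0.901, 0.999)
    noise_score_range: tuple[float, float] = (0.150, 0.899)
    degree_tail_exponent: float = 2.5
    max_degree: int = 80
    planted_groups: tuple[PlantedGroup, ...] = (
        PlantedGroup((0, 1, 2), shared_drugs=12, shared_proteins=2),
        PlantedGroup((3, 4, 5, 6, 7, 8), shared_drugs=1, shared_proteins=7),
    )
    planted_candidate: PlantedCandidate = PlantedCandidate()
    isolated_diseases: tuple[int, ...] = (15, 16, 17, 18)
    noise: NoiseCounts = NoiseCounts()

    def validate(self) -> None:
        planted = [i for g in self.planted_groups for i in g.members]
        if len(set(planted)) != len(planted):
            raise InfeasibleError("planted groups overlap")
        if set(planted) & set(self.isolated_diseases):
            raise InfeasibleError("planted group member marked isolated")
        all_special = set(planted) | set(self.isolated_diseases)
        if any(i < 0 or i >= self.n_diseases for i in all_special):
            raise InfeasibleError("disease index out of range")
        if len(all_special) >= self.n_diseases:
            raise InfeasibleError("no background disease left to host the "
                                  "candidate target")
        group_prots = sum(g.shared_proteins for g in self.planted_groups)
        background = (self.n_amyloidogenic - len(self.isolated_diseases)
                      - group_prots)
        if background < 1:
            raise InfeasibleError("amyloidogenic protein pool exhausted")
        if not 0 <= self.planted_candidate.protein_index < background:
            raise InfeasibleError("candidate protein index outside the "
                                  "background pool")
        if not 0 <= self.planted_candidate.drug_index < self.n_drugs:
            raise InfeasibleError("candidate drug index out of range")
        if self.planted_candidate.bridge_degree < 2:
            raise InfeasibleError("bridge degree must be >= 2")
        group_drugs = sum(g.shared_drugs for g in self.planted_groups)
        n_private = len(planted)
        if group_drugs + n_private + 1 > self.n_drugs:
            raise InfeasibleError("drug pool exhausted by planted structure")
        if self.n_interactors < _MODULE_A_INTERACTORS + _MODULE_B_INTERACTORS + 4:
            raise InfeasibleError("too few interactors for the modules")


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover, derived by
    independent set-based bookkeeping on the generated rows."""

    seed: int
    n_nodes: int
    n_edges: int
    n_dp_edges: int
    n_pp_edges: int
    n_pd_edges: int
    n_dd_edges: int
    ppi_drops: dict[str, int]
    dp_drops: dict[str, int]
    drug_drops: dict[str, int]
    planted_groups: list[dict]
    planted_candidate: dict
    isolated_disease_ids: list[str]
    interactor_degrees: list[int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _sample_powerlaw_degrees(rng, n, gamma, dmax):
    """Discrete power-law degrees via inverse-CDF on P(k) ∝ k^-gamma."""
    ks = np.arange(1, dmax + 1, dtype=float)
    pmf = ks ** (-gamma)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, dmax + 1), size=n, p=pmf)


def _stub_match(rng, nodes, degrees):
    """Configuration-model stub matching; clashes rewired by reshuffling
    leftover stubs a few rounds, then dropped."""
    stubs = []
    for node, d in zip(nodes, degrees):
        stubs.extend([node] * int(d))
    if len(stubs) % 2:
        stubs.pop()
    edges: set[tuple[str, str]] = set()
    for _ in range(5):
        rng.shuffle(stubs)
        leftover = []
        for a, b in zip(stubs[::2], stubs[1::2]):
            pair = (a, b) if a < b else (b, a)
            if a == b or pair in edges:
                leftover.extend([a, b])
            else:
                edges.add(pair)
        stubs = leftover
        if len(stubs) < 2:
            break
    return edges


def _largest_component(adj: dict[str, set[str]]) -> list[str]:
    """Largest connected component by flood fill (sorted for determinism)."""
    seen: set[str] = set()
    best: list[str] = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(comp) > len(best):
            best = comp
    return sorted(best)


def _cap_pairs(scores: dict[tuple[str, str], float], max_neighbors: int):
    """Independent re-statement of the neighbor cap (top-N by score,
    lexicographic tie-break, both endpoints must agree)."""
    partners: dict[str, list[tuple[float, str]]] = {}
    for (a, b), s in scores.items():
        partners.setdefault(a, []).append((s, b))
        partners.setdefault(b, []).append((s, a))
    top = {
        n: {p for _, p in sorted(pl, key=lambda t: (-t[0], t[1]))[:max_neighbors]}
        for n, pl in partners.items()
    }
    return {pair: s for pair, s in scores.items()
            if pair[1] in top[pair[0]] and pair[0] in top[pair[1]]}


def generate(
    config: SyntheticConfig, outdir: str | Path,
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the four ingest inputs (+ XML dialect + ground-truth JSON).

    Returns the file paths and the :class:`GroundTruth` object.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---------------- id pools ----------------
    n_prot = config.n_amyloidogenic + config.n_codeposited + config.n_interactors
    prot_ids = [f"P{i:05d}" for i in range(1, n_prot + 1)]
    amy = prot_ids[:config.n_amyloidogenic]
    cod = prot_ids[config.n_amyloidogenic:
                   config.n_amyloidogenic + config.n_codeposited]
    inter = prot_ids[config.n_amyloidogenic + config.n_codeposited:]

    n_iso = len(config.isolated_diseases)
    iso_prots = amy[len(amy) - n_iso:] if n_iso else []
    remaining_amy = amy[:len(amy) - n_iso]
    group_prots: list[list[str]] = []
    for g in config.planted_groups:
        group_prots.append(remaining_amy[len(remaining_amy) - g.shared_proteins:])
        remaining_amy = remaining_amy[:len(remaining_amy) - g.shared_proteins]
    background_amy = remaining_amy
    target = background_amy[config.planted_candidate.protein_index]
    draw_amy = [p for p in background_amy if p != target]

    mod_a = inter[:_MODULE_A_INTERACTORS]
    mod_b = inter[_MODULE_A_INTERACTORS:
                  _MODULE_A_INTERACTORS + _MODULE_B_INTERACTORS]
    main_inter = inter[_MODULE_A_INTERACTORS + _MODULE_B_INTERACTORS:]

    disease_ids = [f"disease-{i:02d}" for i in range(config.n_diseases)]
    disease_names = {d: f"Synthetic amyloidosis {i:02d}"
                     for i, d in enumerate(disease_ids)}
    planted_members = [i for g in config.planted_groups for i in g.members]
    iso_ids = [disease_ids[i] for i in config.isolated_diseases]
    background = [d for i, d in enumerate(disease_ids)
                  if i not in planted_members
                  and i not in config.isolated_diseases]
    host = background[0]

    drug_ids = [f"DB{10000 + i}" for i in range(config.n_drugs)]
    cand_drug = drug_ids[config.planted_candidate.drug_index]
    free_drugs = [d for d in drug_ids if d != cand_drug]
    group_drugs: list[list[str]] = []
    for g in config.planted_groups:
        group_drugs.append(free_drugs[len(free_drugs) - g.shared_drugs:])
        free_drugs = free_drugs[:len(free_drugs) - g.shared_drugs]
    private_drugs = free_drugs[len(free_drugs) - len(planted_members):]
    free_drugs = free_drugs[:len(free_drugs) - len(planted_members)]
    n_decoys = min(6, len(draw_amy), max(0, len(free_drugs) - 90))
    decoy_drugs = free_drugs[:n_decoys]
    indication_pool = free_drugs[n_decoys:n_decoys + 24]
    target_drug_pool = free_drugs[n_decoys + 24:n_decoys + 84]

    # ---------------- wiring (bookkeeping sets) ----------------
    dp_role: dict[tuple[str, str], str] = {}       # (disease, protein) -> role
    dd_pairs: set[tuple[str, str]] = set()         # (drug, disease)
    pd_pairs: set[tuple[str, str]] = set()         # (drug, protein)

    for g, prots, drugs in zip(config.planted_groups, group_prots, group_drugs):
        for i in g.members:
            d = disease_ids[i]
            for p in prots:
                dp_role[(d, p)] = AMYLOIDOGENIC
            for dr in drugs:
                dd_pairs.add((dr, d))
    for member, priv in zip(planted_members, private_drugs):
        dd_pairs.add((priv, disease_ids[member]))

    for d, p in zip(iso_ids, iso_prots):
        dp_role[(d, p)] = AMYLOIDOGENIC

    for d in background:
        k_a = int(rng.integers(1, 4))
        picks = list(rng.choice(draw_amy, size=min(k_a, len(draw_amy)),
                                replace=False))
        if d == host:
            picks.append(target)
        for p in picks:
            dp_role[(d, p)] = AMYLOIDOGENIC
        k_c = int(rng.integers(0, 3))
        if k_c and cod:
            for p in rng.choice(cod, size=min(k_c, len(cod)), replace=False):
                dp_role[(d, p)] = CO_DEPOSITED
        k_dr = int(rng.integers(1, 5))
        for dr in rng.choice(indication_pool, size=min(k_dr, len(indication_pool)),
                             replace=False):
            dd_pairs.add((dr, d))

    # PPI: module cliques + power-law main graph + anchoring edges
    pp_pairs: set[tuple[str, str]] = set()

    def clique(nodes):
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                pp_pairs.add((a, b) if a < b else (b, a))

    clique([target] + mod_a)
    clique(mod_b)

    dmax = min(config.max_degree, len(main_inter) - 1)
    degrees = _sample_powerlaw_degrees(
        rng, len(main_inter), config.degree_tail_exponent, dmax)
    main_edges = _stub_match(rng, main_inter, degrees)
    pp_pairs |= main_edges

    # anchor disease proteins to the giant component of the interactor
    # graph so only the deliberately isolated diseases stay unconnected
    adj: dict[str, set[str]] = {}
    for a, b in main_edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    giant = _largest_component(adj) or list(main_inter)
    anchors = draw_amy + cod + [p for prots in group_prots for p in prots]
    for p in anchors:
        k = int(rng.integers(1, 3))
        for q in rng.choice(giant, size=min(k, len(giant)), replace=False):
            pp_pairs.add((p, q) if p < q else (q, p))

    lo, hi = config.ppi_score_range
    pp_scores = {pair: round(float(rng.uniform(lo, hi)), 3)
                 for pair in sorted(pp_pairs)}

    # drug targets
    pd_pairs.add((cand_drug, target))
    for b_prot in mod_b[:config.planted_candidate.bridge_degree - 1]:
        pd_pairs.add((cand_drug, b_prot))
    for i, dr in enumerate(decoy_drugs):
        pd_pairs.add((dr, draw_amy[i % len(draw_amy)]))
    n_targeted = min(40, len(main_inter), len(target_drug_pool))
    targeted = rng.choice(main_inter, size=n_targeted, replace=False)
    for dr, p in zip(target_drug_pool, targeted):
        pd_pairs.add((dr, p))

    # ---------------- table rows (with noise) ----------------
    nz = config.noise
    dp_rows = [[d, p, role] for (d, p), role in sorted(dp_role.items())]
    dup_dp = [dp_rows[i] for i in
              rng.choice(len(dp_rows), size=min(nz.duplicate_dp, len(dp_rows)),
                         replace=False)]
    dp_rows_out = dp_rows + [list(r) for r in dup_dp]

    ppi_rows = [[a, b, f"{s:.3f}", "9606"]
                for (a, b), s in sorted(pp_scores.items())]
    kept_list = sorted(pp_scores.items())
    dup_idx = rng.choice(len(kept_list),
                         size=min(nz.duplicate_ppi, len(kept_list)),
                         replace=False)
    dup_ppi = [[kept_list[i][0][1], kept_list[i][0][0],
                f"{kept_list[i][1]:.3f}", "9606"] for i in dup_idx]
    nlo, nhi = config.noise_score_range
    sub_rows = []
    for _ in range(nz.subthreshold):
        a, b = rng.choice(prot_ids, size=2, replace=False)
        s = min(round(float(rng.uniform(nlo, nhi)), 3), 0.899)
        sub_rows.append([a, b, f"{s:.3f}", "9606"])
    nonhuman_rows = []
    for _ in range(nz.nonhuman):
        a, b = rng.choice(prot_ids, size=2, replace=False)
        s = round(float(rng.uniform(lo, hi)), 3)
        nonhuman_rows.append([a, b, f"{s:.3f}", "10090"])
    ppi_rows_out = ppi_rows + dup_ppi + sub_rows + nonhuman_rows

    target_rows = [[dr, p] for dr, p in sorted(pd_pairs)]
    metal_rows = [[METAL_DRUG_IDS[i % len(METAL_DRUG_IDS)],
                   str(rng.choice(main_inter))] for i in range(nz.metal)]
    dup_targets = [target_rows[i] for i in
                   rng.choice(len(target_rows),
                              size=min(nz.duplicate_target, len(target_rows)),
                              replace=False)]
    target_rows_out = target_rows + metal_rows + [list(r) for r in dup_targets]

    ind_rows = [[dr, d] for dr, d in sorted(dd_pairs)]
    dup_ind = [ind_rows[i] for i in
               rng.choice(len(ind_rows),
                          size=min(nz.duplicate_indication, len(ind_rows)),
                          replace=False)]
    ind_rows_out = ind_rows + [list(r) for r in dup_ind]

    for rows in (dp_rows_out, ppi_rows_out, target_rows_out, ind_rows_out):
        rng.shuffle(rows)

    # ---------------- write files ----------------
    paths = {
        "disease_protein_tsv": outdir / "disease_protein.tsv",
        "disease_protein_xml": outdir / "disease_protein.xml",
        "ppi_tsv": outdir / "ppi.tsv",
        "drug_targets_tsv": outdir / "drug_targets.tsv",
        "drug_indications_tsv": outdir / "drug_indications.tsv",
        "ground_truth_json": outdir / "ground_truth.json",
    }
    _write_tsv(paths["disease_protein_tsv"],
               ["disease_id", "uniprot_ac", "role"], dp_rows_out)
    _write_tsv(paths["ppi_tsv"],
               ["protein_a", "protein_b", "combined_score", "organism_tag"],
               ppi_rows_out)
    _write_tsv(paths["drug_targets_tsv"],
               ["drugbank_id", "uniprot_ac"], target_rows_out)
    _write_tsv(paths["drug_indications_tsv"],
               ["drugbank_id", "disease_id"], ind_rows_out)
    _write_dp_xml(paths["disease_protein_xml"], dp_rows_out, disease_names)

    # ---------------- ground truth ----------------
    capped = _cap_pairs(pp_scores, 100)
    dropped_cap = len(pp_scores) - len(capped)

    nbrs: dict[str, set[str]] = {d: set() for d in disease_ids}
    for (d, p) in dp_role:
        nbrs[d].add(p)
    for (dr, d) in dd_pairs:
        nbrs[d].add(dr)

    node_ids = set(disease_ids)
    for (d, p) in dp_role:
        node_ids.add(p)
    for a, b in capped:
        node_ids.update((a, b))
    for dr, p in pd_pairs:
        node_ids.update((dr, p))
    for dr, d in dd_pairs:
        node_ids.add(dr)

    n_edges = len(dp_role) + len(capped) + len(pd_pairs) + len(dd_pairs)

    gt_groups = []
    for g, prots, drugs in zip(config.planted_groups, group_prots, group_drugs):
        members = sorted(disease_ids[i] for i in g.members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if len(nbrs[a] & nbrs[b]) != g.pair_weight:
                    raise InfeasibleError(
                        f"planted weight violated for ({a}, {b})")
        gt_groups.append({
            "members": members,
            "pair_weight": g.pair_weight,
            "shared_drugs": g.shared_drugs,
            "shared_proteins": g.shared_proteins,
        })

    cand_diseases = sorted(
        d for (d, p) in dp_role if p == target and (cand_drug, d) not in dd_pairs
    )
    degseq = {}
    for a, b in capped:
        degseq[a] = degseq.get(a, 0) + 1
        degseq[b] = degseq.get(b, 0) + 1
    interactor_degrees = sorted(
        (degseq.get(p, 0) for p in main_inter), reverse=True)

    gt = GroundTruth(
        seed=config.seed,
        n_nodes=len(node_ids),
        n_edges=n_edges,
        n_dp_edges=len(dp_role),
        n_pp_edges=len(capped),
        n_pd_edges=len(pd_pairs),
        n_dd_edges=len(dd_pairs),
        ppi_drops={
            "records_in": len(ppi_rows_out),
            "dropped_self": 0,
            "dropped_nonhuman": len(nonhuman_rows),
            "dropped_below_min_score": len(sub_rows),
            "dropped_duplicate": len(dup_ppi),
            "dropped_neighbor_cap": dropped_cap,
            "records_out": len(capped),
        },
        dp_drops={
            "records_in": len(dp_rows_out),
            "dropped_duplicate": len(dup_dp),
            "records_out": len(dp_role),
        },
        drug_drops={
            "targets_in": len(target_rows_out),
            "targets_dropped_excluded": len(metal_rows),
            "targets_dropped_duplicate": len(dup_targets),
            "targets_out": len(pd_pairs),
            "indications_in": len(ind_rows_out),
            "indications_dropped_excluded": 0,
            "indications_dropped_duplicate": len(dup_ind),
            "indications_out": len(dd_pairs),
        },
        planted_groups=gt_groups,
        planted_candidate={
            "drug_id": cand_drug,
            "target_ids": sorted(p for dr, p in pd_pairs if dr == cand_drug),
            "amyloidogenic_target": target,
            "candidate_diseases": cand_diseases,
        },
        isolated_disease_ids=sorted(iso_ids),
        interactor_degrees=interactor_degrees,
    )
    paths["ground_truth_json"].write_text(gt.to_json() + "\n", encoding="utf-8")
    return paths, gt


@dataclass
class VerificationReport:
    """Itemised comparison of a pipeline run against ground truth."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, bool, str]]:
        return [c for c in self.checks if not c[1]]

    def to_json(self) -> str:
        return json.dumps(
            {"passed": self.passed,
             "checks": [{"name": n, "ok": ok, "detail": d}
                        for n, ok, d in self.checks]},
            indent=2)


def verify_pipeline(fixture_dir: str | Path,
                    ground_truth: GroundTruth) -> VerificationReport:
    """Run the full pipeline on generated fixtures and compare every
    stage's output against the ground truth."""
    from . import assembly, disease_projection, drug_repurposing, ingest

    fixture_dir = Path(fixture_dir)
    report = VerificationReport()
    names = {
        "dp": "disease_protein.tsv", "ppi": "ppi.tsv",
        "targets": "drug_targets.tsv", "ind": "drug_indications.tsv",
    }
    missing = [f for f in names.values() if not (fixture_dir / f).exists()]
    if missing:
        report.add("files_present", False, f"missing: {', '.join(missing)}")
        return report
    report.add("files_present", True)

    ppi_stats: dict = {}
    drug_stats: dict = {}
    dp_stats: dict = {}
    dp_edges, nodes = ingest.read_disease_protein_associations(
        fixture_dir / names["dp"], dialect="tsv", stats=dp_stats)
    pp = ingest.read_ppi_table(fixture_dir / names["ppi"], stats=ppi_stats)
    pd_edges, dd = ingest.read_drug_tables(
        fixture_dir / names["targets"], fixture_dir / names["ind"],
        stats=drug_stats)

    report.add("dp_edge_count", len(dp_edges) == ground_truth.n_dp_edges,
               f"{len(dp_edges)} vs {ground_truth.n_dp_edges}")
    report.add("pp_edge_count", len(pp) == ground_truth.n_pp_edges,
               f"{len(pp)} vs {ground_truth.n_pp_edges}")
    report.add("pd_edge_count", len(pd_edges) == ground_truth.n_pd_edges,
               f"{len(pd_edges)} vs {ground_truth.n_pd_edges}")
    report.add("dd_edge_count", len(dd) == ground_truth.n_dd_edges,
               f"{len(dd)} vs {ground_truth.n_dd_edges}")
    report.add("dp_filter_drops", dp_stats == ground_truth.dp_drops,
               f"{dp_stats} vs {ground_truth.dp_drops}")
    report.add("ppi_filter_drops", ppi_stats == ground_truth.ppi_drops,
               f"{ppi_stats} vs {ground_truth.ppi_drops}")
    report.add("drug_filter_drops", drug_stats == ground_truth.drug_drops,
               f"{drug_stats} vs {ground_truth.drug_drops}")

    net = assembly.build_network(dp_edges, pp, pd_edges, dd,
                                 node_records=nodes)
    report.add("node_count", net.number_of_nodes() == ground_truth.n_nodes,
               f"{net.number_of_nodes()} vs {ground_truth.n_nodes}")
    report.add("edge_count", net.number_of_edges() == ground_truth.n_edges,
               f"{net.number_of_edges()} vs {ground_truth.n_edges}")

    comp = assembly.connected_components(net)
    report.add("isolated_diseases",
               comp.isolated_disease_ids == ground_truth.isolated_disease_ids,
               f"{comp.isolated_disease_ids}")

    matrix = disease_projection.common_neighbor_matrix(net)
    dnet = disease_projection.build_disease_network(matrix)
    groups = disease_projection.find_dense_groups(dnet, min_size=3,
                                                  hetero_net=net)
    found = {g.member_ids: g for g in groups}
    for spec_g in ground_truth.planted_groups:
        members = tuple(spec_g["members"])
        g = found.get(members)
        ok = (g is not None
              and g.min_internal_weight == spec_g["pair_weight"]
              and g.shared_neighbors is not None
              and g.shared_neighbors.n_drugs == spec_g["shared_drugs"]
              and g.shared_neighbors.n_proteins == spec_g["shared_proteins"])
        report.add(f"group_{'_'.join(members)}", ok,
                   "missing" if g is None else
                   f"min_w={g.min_internal_weight} vs {spec_g['pair_weight']}")

    centrality = drug_repurposing.betweenness(net)
    candidates = drug_repurposing.candidate_filter(net)
    ranked = drug_repurposing.rank_candidates(candidates, centrality)
    gt_cand = ground_truth.planted_candidate
    top = ranked[0] if ranked else None
    report.add("candidate_rank_1",
               top is not None and top.drug_id == gt_cand["drug_id"],
               "no candidates" if top is None else f"top={top.drug_id}")
    if top is not None and top.drug_id == gt_cand["drug_id"]:
        report.add("candidate_diseases",
                   top.candidate_diseases == gt_cand["candidate_diseases"],
                   f"{top.candidate_diseases}")
    return report


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# synthetic fixture (generated)\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _write_dp_xml(path: Path, dp_rows, disease_names) -> None:
    """Equivalent XML dialect of the disease-protein table."""
    by_disease: dict[str, list[tuple[str, str]]] = {}
    for d, p, role in dp_rows:
        by_disease.setdefault(d, []).append((p, role))
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<diseases>"]
    for d in sorted(by_disease):
        name = disease_names.get(d, d)
        lines.append(f'  <disease id="{d}" name="{name}">')
        for p, role in by_disease[d]:
            lines.append(f'    <protein ac="{p}" role="{role}"/>')
        lines.append("  </disease>")
    lines.append("</diseases>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
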