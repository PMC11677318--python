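import itertools

import networkx as nx
import numpy as np
import pytest

from amyloidnet.synthetic_data import SyntheticConfig, generate

FIXTURE_SEED = 20240917


@pytest.fixture(scope="session")
def default_fixtures(tmp_path_factory):
    """Default-configuration synthetic dataset shared across the suite."""
    outdir = tmp_path_factory.mktemp("fixtures")
    config = SyntheticConfig(seed=FIXTURE_SEED)
    paths, gt = generate(config, outdir)
    return outdir, paths, gt, config


def make_hetero(dp=(), pp=(), pd=(), dd=()):
    """Small hand-built heterogeneous network for unit tests.

    dp: (disease, protein, roles) triples; pp: (a, b[, score]); pd:
    (protein, drug); dd: (disease, drug).
    """
    g = nx.Graph()

    def node(nid, category):
        if nid not in g:
            g.add_node(nid, category=category, protein_roles=frozenset(),
                       display_name=nid)

    for d, p, *roles in dp:
        node(d, "disease")
        node(p, "protein")
        g.add_edge(d, p, edge_type="disease-protein")
        if roles:
            g.nodes[p]["protein_roles"] = (
                g.nodes[p]["protein_roles"] | frozenset(roles[0]))
    for a, b, *score in pp:
        node(a, "protein")
        node(b, "protein")
        g.add_edge(a, b, edge_type="protein-protein",
                   score=score[0] if score else 0.95)
    for p, dr in pd:
        node(p, "protein")
        node(dr, "drug")
        g.add_edge(p, dr, edge_type="protein-drug")
    for d, dr in dd:
        node(d, "disease")
        node(dr, "drug")
        g.add_edge(d, dr, edge_type="disease-drug")
    return g


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately naive and independent of the
# implementation's code paths


def brute_clustering(g: nx.Graph) -> float:
    total = 0.0
    for v in g:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k)
            if g.has_edge(nb[i], nb[j])
        )
        total += 2.0 * links / (k * (k - 1))
    return total / g.number_of_nodes()


def brute_paths(g: nx.Graph):
    """(CPL over connected pairs, diameter) by Floyd-Warshall on a dense
    distance matrix."""
    nodes = sorted(g)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in g.edges():
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    off = dist[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        return None, None
    return float(finite.mean()), int(finite.max())


def brute_betweenness(g: nx.Graph, normalized: bool = True):
    """Betweenness by explicit enumeration of all shortest simple paths."""
    nodes = sorted(g)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        shortest = [p for p in nx.all_simple_paths(g, s, t, cutoff=d)
                    if len(p) == d + 1]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    if normalized:
        n = len(nodes)
        denom = (n - 1) * (n - 2) / 2.0
        if denom > 0:
            bc = {v: b / denom for v, b in bc.items()}
    return bc


def brute_common_neighbors(g: nx.Graph, disease_ids):
    """Shared-neighbor counts via 0/1 incidence-matrix multiplication."""
    others = sorted(n for n, c in g.nodes(data="category") if c != "disease")
    col = {v: j for j, v in enumerate(others)}
    a = np.zeros((len(disease_ids), len(others)), dtype=int)
    for i, d in enumerate(disease_ids):
        for nb in g.neighbors(d):
            if nb in col:
                a[i, col[nb]] = 1
    w = a @ a.T
    np.fill_diagonal(w, 0)
    return w
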