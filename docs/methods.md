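# Methods

## The model

The object of study is a simple undirected heterogeneous graph with
three node categories (disease, protein, drug) and four edge relations:
disease–protein deposition associations (each tagged with the protein's
role in that disease, amyloidogenic or co-deposited), protein–protein
interactions carrying a combined confidence score, protein–drug target
relations, and disease–drug indications. Node id namespaces are
disjoint by construction (disease slugs, UniProt-style accessions,
DrugBank-style `DB`+5-digit accessions), so "one edge per unordered
pair" coincides with "one edge per (pair, relation)"; an id observed
under two categories is treated as corrupt input and rejected rather
than coerced.

Protein roles compose: a protein can be amyloidogenic in one disease,
co-deposited in another, and a drug target throughout. Role tags are
kept per edge and unioned per node. Proteins that appear only in PPI
edges are tagged `interactor`; every drug-targeted protein additionally
carries `drug_target`.

## Ingest filters

The PPI table is reduced to a high-confidence human physical
subnetwork. The filter chain, in order: score-scale normalisation
(any value > 1 implies the 0–1000 integer dialect; all values are then
divided by 1000), self-pair removal, organism filter (keep tag `9606`),
confidence floor (default 0.900, **inclusive** — a "minimum required
score" reads as a floor), pair de-duplication keeping the **maximum**
score (conservative toward retaining evidence), and a neighbor cap
(default 100). The cap keeps an edge only when *each* endpoint ranks
the other among its top-N partners by (score desc, partner id asc);
the one-sided alternative would fail to cap a hub whose partners are
themselves low-degree. The chain is a projection: applying it to its
own output changes nothing. Each stage reports records-in/dropped/out
counts, attributing every dropped row to the first rule that removes
it.

Drug tables pass through a configurable blocklist seeded with the
DrugBank accessions of zinc, copper and aluminium — substances that
bind very many proteins non-specifically and would otherwise dominate
the target network. Ids that do not match the `DB`+5-digit pattern are
kept but logged, since fixture data may use foreign id schemes.

## Topological statistics

All statistics follow the conventions of the NetworkAnalyzer lineage of
tools, because those are the numbers practitioners compare against:

* density 2E/(N(N−1)); average neighbors 2E/N;
* mean local clustering with degree-0/1 nodes contributing 0 and
  **included** in the average (this choice lowers the statistic on
  star-heavy graphs and is therefore stated explicitly);
* characteristic path length averaged over **connected ordered pairs
  only**, so networks with isolated components still get a finite
  value; diameter is the largest finite shortest path;
* heterogeneity as the coefficient of variation of the degree sequence
  (population variance).

### Power-law fit

The degree distribution is fitted to a discrete power law
P(k) = k^(−γ)/ζ(γ, x_min) by maximising the exact discrete likelihood
(Hurwitz-zeta normalisation, bounded scalar minimisation of the
negative log-likelihood over γ ∈ (1, 8]); x_min is chosen by scanning
the observed degree values and minimising the KS distance between the
model CDF and the empirical tail CDF. Two constants are reported: the
MLE exponent (the statistically meaningful one) and a least-squares
intercept constant from regressing log P(k) on log k over the full
empirical distribution, because degree-distribution reports in the
applied literature usually print that regression constant.

Flags: `hub_regime` is γ < 2 (hubs carry network integrity),
`reliable` requires ≥ 50 tail points, and `scale_free` uses the
rule-of-thumb KS threshold 1.36/√n_tail. The last is a **screen, not a
hypothesis test**: with a free x_min, a non-power-law sample can pass
on its far tail (a geometric sample, for instance, passes with a large
x_min and an absurd γ ≈ 6.5, though its KS distance is still ~25×
worse than a genuine power-law sample of equal size). The test suite
therefore checks KS ordering between distributions rather than the
flag alone; bootstrap p-values are deliberately out of scope.

### Null model

The random reference is Erdős–Rényi G(N, M) with the observed node and
edge counts — matching how same-size random comparisons are usually
produced — rather than degree-preserving rewiring; replicate *i* uses
seed `seed + i`, so the comparison is bit-reproducible. Default 10
replicates with mean ± sd per statistic (a single replicate is allowed
but gives sd 0). Classification defaults: sparse ⇔ density < 0.1;
small-world ⇔ observed clustering ≥ 10× the null mean **and** observed
path length ≤ 1.5× the null mean. Both factors are configurable; 10×
is deliberately conservative (real biological networks typically show
50–100×), and 1.5× tolerates the mild path-length inflation that
clustering induces.

## Disease projection

A disease's first-neighbor set contains its adjacent proteins and
drugs; other disease nodes are excluded (diseases relate only through
molecular intermediates here). The common-neighbor matrix
w_ij = |N(i) ∩ N(j)| is symmetric with a masked diagonal — masking
rather than storing |N(i)| prevents accidental self-edges downstream.
Zero-weight pairs carry no edge in the projected disease network, but
every disease remains a node, so isolated diseases stay visible.

Dense-group discovery is formalised as maximal-clique enumeration
(Bron–Kerbosch via networkx) with ranking key (minimum internal weight
desc, total internal weight desc, lexicographic members). The minimum
internal weight leads because a group is only as coherent as its
weakest pair; a three-disease clique sharing 14 neighbors pairwise
therefore outranks a six-disease clique sharing 8.

## Drug repurposing

Candidate predicate, checked against raw edges: (a) ≥ 1 protein–drug
edge to an amyloidogenic-role protein; (b) ≥ 1 disease of such a
target with **no** disease–drug edge to the drug; (c) not on the
user-supplied exclusion list. The exclusion list is the
machine-checkable stand-in for a manual literature screen; excluded
drugs are still returned with a flag, so the pass/fail record is
auditable, but they are skipped in ranking. Ranking is by exact Brandes
betweenness on the full heterogeneous network with all edges
unweighted (whole-network ranking; a per-disease-subnetwork variant
would be a straightforward restriction but the global bridge role is
the signal of interest). Ties break lexicographically. Two-hop context
subnetworks may layer in medium-confidence PPIs (0.700 ≤ s < 0.900) as
a tier-tagged display layer; these edges extend the visible context
but never enter centrality or projection.

## Synthetic data generator

The generator emulates, at roughly quarter scale, the shape of a
released amyloidosis dataset: 19 diseases, 24 amyloidogenic + 12
co-deposited + 160 interactor proteins, a 350-drug pool (of which
~100 acquire edges), kept PPI scores uniform on [0.901, 0.999], and
noise rows spanning the rest of the 0.150–0.999 score range. The
quarter scale keeps the full suite fast; counts scale up cleanly (a
76-disease configuration is exercised in the tests).

Structural choices:

* **Interactor degrees** are drawn from a discrete power law (default
  γ = 2.5 — a typical PPI tail exponent that also has a finite mean,
  unlike γ < 2, which would make stub matching degenerate), capped at
  80 by default, and wired by configuration-model stub matching with
  clashes reshuffled for up to five rounds, then dropped.
* **Planted groups** (a triangle sharing 12 drugs + 2 amyloidogenic
  proteins; a six-clique sharing 1 drug + 7 proteins) are wired
  *exclusively*: members touch only their shared nodes plus one
  private drug each, so every pairwise weight equals the planted sum
  exactly and recovery assertions can be equalities, not bounds.
* **The planted candidate drug** targets one amyloidogenic protein
  (held by a background "host" disease) and is the sole connector to a
  7-protein clique that touches nothing else; every shortest path from
  that module to the rest of the giant component crosses the drug,
  guaranteeing it the top betweenness among drugs by construction.
* **Isolated diseases** (4, each with one private protein) form
  components disjoint from the giant one. All other disease proteins
  are anchored to the giant component of the interactor graph —
  necessary because a γ = 2.5 configuration model produces many dimer
  fragments that would otherwise strand random diseases.
* **Noise rows** (defaults: 40 sub-threshold, 15 non-human, 6 metal,
  23 duplicates across tables) are constructed so each is removed by
  exactly one ingest rule, making drop-count bookkeeping exact:
  non-human rows get high scores (human filter fires first),
  sub-threshold rows are human, duplicates replicate surviving rows.

Ground truth is computed by independent set-based bookkeeping on the
generated rows (plain Python sets, including a re-statement of the
neighbor cap), not by calling the ingest code path. Identical
(config, seed) yields byte-identical files.

What the generator does **not** emulate: the real network's printed
statistics (clustering 0.158, γ ≈ 1.4), which depend on database
snapshots; correlated disease–protein co-occurrence beyond the planted
groups; score–degree correlation; literature co-citation structure. A
green suite therefore demonstrates algorithmic correctness and planted
-structure recovery, not fidelity to any particular database release.
At quarter scale the small-world flag is typically *not* asserted by
the synthetic network (its clustering ratio runs ~5× against the 10×
criterion); the flag's logic is instead tested on Watts–Strogatz
constructions where the expected answer is known.

## Numerical and degenerate-input conventions

Density needs N ≥ 2; path statistics need ≥ 1 connected pair;
heterogeneity needs a nonzero degree; the power-law fit needs ≥ 2
distinct positive degrees — each violation raises a typed error rather
than returning NaN. Betweenness on N < 3 returns all zeros by
convention (the normalisation divisor vanishes). Degree rankings and
all tie-breaks are lexicographic, so every output is deterministic.
Matrix TSVs, GraphML and JSON reports are written with sorted keys and
fixed float formats; reruns on unchanged inputs are byte-identical.

## Problem sizes used in the automated checks

Oracle-equivalence runs use 200 random graphs of 4–30 nodes (4–10 for
path-enumeration betweenness); exponent recovery uses 10,000 samples at
γ = 2.5 (tolerance ±0.1) and a 5,000-interactor generator run
(tolerance ±0.15); the null-model sanity bound uses N=100, M=300 with
20 replicates; end-to-end recovery uses the default quarter-scale
configuration. These sizes were chosen as the smallest at which each
statistical property is stable.
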