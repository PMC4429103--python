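# Methods

## Enrichment model

The overlap test is the one-sided hypergeometric upper tail,
P(X ≥ k) with X ~ Hypergeometric(N, K, n), computed with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`.  This equals the one-sided
Fisher's exact p for the 2×2 table, so either name describes the same test;
only enrichment is tested, never depletion.  k = 0 returns exactly 1.

The background universe defaults to the union of all member genes in the
supplied collection, because commercial pathway databases rarely publish
their background; an explicit universe file overrides this, and the
synthetic generator always writes one (a GMT alone under-counts N and
silently discards candidates outside any pathway).  Candidates outside the
universe are excluded from the test but kept in reports, with a logged
count.

Benjamini–Hochberg adjustment is the standard step-up: sort ascending,
multiply p₍ᵢ₎ by m/i, take the running minimum from the largest rank down,
cap at 1.  The correction family is, by default, the sets with at least one
candidate hit — matching tools that first extract overlapping sets and
correct across those — and can be set to the whole collection.  The adjusted
threshold is strict (P_BH < 0.01).

## Crosstalk scoring

Edges are scored on the **candidate hits** of each pathway, not full
membership: JC = |A∩B|/|A∪B|, OC = |A∩B|/min(|A|,|B|), score = (JC+OC)/2
(arithmetic mean; since JC ≤ OC always, the score lies between them).  The
cascade defaults are ≥ 5 hits per pathway, P_BH < 0.01, ≥ 3 shared hits per
pair, top 20% of scores.  The 20% cut keeps ⌈0.2·|edges|⌉ edges and never
splits tied scores: all edges tying with the score at the cut are kept and
the expansion is logged.  Scores are carried at full precision; two-decimal
rounding is display only.

## Steiner extraction

The heuristic is greedy tree merging on an unweighted host graph: one
singleton tree per seed, then repeatedly merge the two trees at minimal
shortest-path distance along that path, recruiting interior nodes as
linkers, until one tree remains per host component (a Steiner forest on
disconnected hosts, with a warning — real interaction networks have
isolates).  Unit edge lengths are used throughout; no node prizes or edge
weights.  Correctness notes:

* Because the globally closest pair is merged first, a connecting path can
  never pass through a third tree's interior (that tree would be strictly
  closer), so the union of merges is always a forest and every leaf is a
  seed.
* Determinism: BFS enqueues sources and neighbors in sorted order, the
  target node minimizes (distance, label), and tree pairs tie-break on
  (distance, smaller endpoint, larger endpoint, path).  Identical inputs
  give identical trees.
* The reported subnetwork is the host subgraph *induced* on the tree's node
  set, so it usually has more edges than nodes − 1.

`steiner_brute_force` is the exact oracle (hosts ≤ 15 nodes): since a tree
on V′ has |V′|−1 edges, minimizing edges equals minimizing recruited nodes,
so linker subsets are enumerated by size and checked for seed connectivity.
The heuristic is within factor 2 of this optimum on random small hosts and
exactly optimal when seeds are pairwise adjacent.

## Topology statistics and the null model

`topology_stats` averages shortest-path distance over unordered *connected*
pairs (finite on disconnected graphs) and local clustering over all nodes
with degree < 2 counted as 0.  The null is plain Erdős–Rényi G(n, m) — the
uniform simple graph with exactly the observed node and edge counts, via
`networkx.gnm_random_graph` — not a degree-preserving rewiring.  Counts use
strict inequalities (n_L: null L strictly smaller; n_C: null C strictly
larger); an empirical p of 0 is reported as "0 (< 1/reps)".  Replicates draw
from substreams spawned off one master seed, recorded in the output, so the
test is bit-reproducible.

One subtlety documented here because a test relies on it: for a G(n, m)
node with degree ≥ 2, the expected local clustering is the conditional edge
density ≈ 2m/(n(n−1)); nodes of degree < 2 have no defined local
clustering, and zero-counting them (as the reported statistic does) biases
the ensemble mean below that closed form.  The calibration test therefore
compares the degree ≥ 2 mean against the density, while the reported
statistic keeps the conventional zero-counting.

## Synthetic data: what it emulates and what it does not

* `gen_pathway_collection` plants pairwise overlaps **constructively**
  (dedicated shared genes per pair, remaining members disjoint), so planted
  intersection sizes are exact and triple intersections are empty.  Real
  pathway collections have nested and higher-order overlaps; tests on these
  collections validate the arithmetic of the cascade, not its behavior on
  deeply redundant databases.
* `gen_candidate_genes` samples without replacement with weight
  `enrichment_factor` (default 10) on genes of the true sets, 1 elsewhere —
  a clean relative-risk model of a prioritized candidate list.  Factor 1 is
  the null; upper-tail p-values are then conservative (discrete test), which
  the calibration test checks one-sidedly.
* `gen_host_with_planted_module` splits seeds into cliques chained by
  linker nodes; consecutive cliques connect only through their linker, and
  the module attaches to the background (G(n, m) by default, preferential
  attachment optionally, since real interaction networks are heavy-tailed)
  through the first linker only.  Every linker is therefore a cut vertex
  between seed clusters, making recovery ground truth unambiguous.  Real
  linker genes are rarely perfect cut vertices, so recovery rates here are
  an upper bound on real-data behavior.
* Default study conditions: 2000-gene universe; six pathways (50–25 genes)
  of which three form an overlapping cluster (planted overlaps 20/15/10)
  and two mirror a near-duplicated pair (24 shared of 25); 100 candidates
  at factor 10; host of 110 nodes / ~237 edges with 8 seeds and 3 linkers.
  These sizes keep every stage's signal recoverable while running in
  seconds.

## Problem sizes used in validation

Oracle agreement for the hypergeometric tail is exhaustive for all N ≤ 25
(tolerance 1e-12); BH is checked against an independent step-up
implementation on 1000 random vectors; the Steiner heuristic against the
exact oracle on 200 random hosts of ≤ 12 nodes with 3–5 seeds; the ER
ensemble at (n = 30, m = 60) × 2000 draws; null-test calibration over 100
repetitions of 100 replicates; linker recovery over 20 seeded 60-node
hosts.  The demonstration pipeline runs 1000 null replicates, matching the
default.

## Known limitations

* The greedy merge order is one of several published variants; tie-breaking
  rules differ between implementations, so node-for-node agreement with
  other Steiner tools is not expected (the tree cost is what is bounded).
* Identifier matching is a single case-folding pass plus an optional
  two-column mapping file; no web services or accession-resolution chains.
* Pathway hierarchy (depth) filtering consumes a precomputed depth table;
  no ontology DAG is built.
* The null model matches only (n, m); degree-preserving nulls are out of
  scope by design.
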