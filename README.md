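# pathcrosstalk

Pathway-crosstalk graphs and Steiner-tree subnetworks for candidate-gene
studies.

Candidate-gene screens for complex phenotypes (the motivating case is
nicotine addiction, with a prioritized list of 220 candidate genes) produce
flat gene lists that are hard to interpret one gene at a time.
`pathcrosstalk` implements the standard systems-biology follow-up as a
tested, reusable pipeline:

1. **Enrichment** — each pathway (gene set) is tested for over-representation
   of the candidate list with the one-sided hypergeometric test
   (equivalently, one-sided Fisher's exact test): for a universe of *N* genes,
   a pathway of size *K*, *n* candidates and *k* hits, *p* = P(X ≥ k) for
   X ~ Hypergeometric(N, K, n).  P-values are Benjamini–Hochberg adjusted
   (*P*<sub>BH</sub>).
2. **Crosstalk** — pathways with ≥ 5 candidate hits and *P*<sub>BH</sub> < 0.01
   are paired; a pair sharing ≥ 3 candidate genes gets an edge scored by the
   mean of the Jaccard coefficient JC = |A∩B| / |A∪B| and the overlap
   coefficient OC = |A∩B| / min(|A|, |B|), computed on the candidate hits A
   and B.  The top 20% of edges by score form the crosstalk graph.
3. **Subnetwork** — the candidates seed a greedy Steiner minimal-tree
   extraction from a protein–protein interaction network: singleton trees are
   repeatedly merged along the shortest host path, recruiting non-seed
   *linker* genes; the result is the host subgraph induced on the final node
   set.
4. **Randomization** — the subnetwork's average shortest-path distance L and
   mean clustering coefficient C are compared with 1000 Erdős–Rényi G(n, m)
   graphs matched on node and edge counts; empirical p-values are
   p\_L = #(L_null < L_obs)/1000 and p\_C = #(C_null > C_obs)/1000.

A synthetic-data module generates gene-set collections with exactly planted
overlaps, candidate lists with a controlled enrichment signal, and host
networks with planted linker nodes, so every stage is testable offline with
known ground truth.

## Worked example

The package bundles the 20 canonical pathways most strongly enriched in the
220 nicotine-addiction candidate genes, with the candidate genes each
contains.  Scoring every qualifying pair:

```python
>>> from pathcrosstalk.datasets import na_pathway_hits_as_results
>>> from pathcrosstalk import build_crosstalk
>>> graph = build_crosstalk(na_pathway_hits_as_results(), min_shared=3)
>>> best = graph.edges[0]
>>> best.set_a, best.set_b
('G-Protein Coupled Receptor Signaling', 'cAMP-mediated signaling')
>>> len(best.shared), round(best.jc, 4), round(best.oc, 4), round(best.score, 2)
(24, 0.9231, 0.96, 0.94)
```

The two top-enriched signaling pathways each contain 25 candidate genes and
share 24 of them (they differ only by AKAP13 vs HTR2A), so JC = 24/26,
OC = 24/25 and the crosstalk score is 0.94 — the highest of all pairs.

A fully synthetic run from the shell:

```sh
pathcrosstalk simulate --seed 7 --outdir demo/inputs
pathcrosstalk pipeline \
    --candidates demo/inputs/candidates.txt \
    --gmt demo/inputs/collection.gmt \
    --universe demo/inputs/universe.txt \
    --network demo/inputs/network.tsv \
    --reps 1000 --seed 7 --outdir demo/out
```

prints (abridged):

```json
{
  "n_sets_filtered": 3,
  "n_crosstalk_edges": 2,
  "subnetwork_nodes": 11,
  "subnetwork_edges": 16,
  "seeds_in": 8,
  "linkers": 3,
  "observed_C": 0.696969696969697,
  "p_C": "0 (< 0.001)"
}
```

The three planted overlapping pathways pass the filters and form the
crosstalk edges; the Steiner stage recovers the 8 planted seeds plus exactly
the 3 planted linker genes; and because the planted module is built from
seed cliques, its clustering coefficient (0.70) beats all 1000
density-matched random graphs (p\_C reported as 0, i.e. < 1/reps).  Each run
writes tab-separated tables, Cytoscape-ready SIF/GraphML exports, and a
`manifest.json` with the seed, thresholds and SHA-256 checksums of every
input and output.

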