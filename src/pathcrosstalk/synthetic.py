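"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three kinds of input:

* gene-set collections with *exactly* planted pairwise overlaps, so crosstalk
  scores on them are known in closed form;
* candidate gene lists sampled without replacement with an elevated weight on
  genes of designated "true" sets, emulating a prioritized disease-gene list
  concentrated in real pathways;
* host networks with seed clusters joined only through planted linker nodes,
  so the ground-truth linker set a Steiner extraction should recover is known.

Overlap planting is constructive (shared genes are assigned, not sampled), so
crosstalk tests are sharp; candidate planting is stochastic, so enrichment
tests are power-style.  All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import GeneSet, GeneSetCollection, write_edge_list, write_gmt

__all__ = [
    "SyntheticSpec",
    "gen_pathway_collection",
    "gen_candidate_genes",
    "gen_host_with_planted_module",
    "write_synthetic_inputs",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults describe a mid-sized candidate-gene screen: a 2000-gene
    universe; six pathways of 25–50 genes of which the first three form a
    strongly overlapping cluster (the crosstalk structure to recover) and
    the last two mirror a near-duplicated pathway pair; a 100-gene candidate
    list drawn with 10-fold weight on the three true pathways; and a
    ~110-node host network carrying 8 seeds in clusters bridged by 3
    linkers.
    """

    rng_seed: int = 0
    universe_size: int = 2000
    set_sizes: Sequence[int] = (50, 40, 40, 30, 25, 25)
    planted_overlaps: Mapping[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 1): 20, (1, 2): 15, (0, 2): 10, (4, 5): 24}
    )
    true_sets: Sequence[str] = ("PW1", "PW2", "PW3")
    enrichment_factor: float = 10.0
    n_candidates: int = 100
    host_model: str = "gnm"  # or "preferential-attachment"
    host_n: int = 110
    host_m: int = 220
    n_seeds: int = 8
    n_true_linkers: int = 3


def _set_name(i: int) -> str:
    return f"PW{i + 1}"


def gen_pathway_collection(spec: SyntheticSpec) -> GeneSetCollection:
    """Build a gene-set collection with exact planted pairwise overlaps.

    Shared genes are dedicated per pair (so triple intersections are empty)
    and remaining members are disjoint across sets; pairwise intersection
    sizes therefore equal the planted counts exactly.
    """
    sizes = list(spec.set_sizes)
    k = len(sizes)
    shared_budget = [0] * k
    for (i, j), c in spec.planted_overlaps.items():
        if not (0 <= i < j < k):
            raise ValueError(f"bad pair index ({i}, {j})")
        if c < 0:
            raise ValueError("planted overlap must be >= 0")
        shared_budget[i] += c
        shared_budget[j] += c
    for i in range(k):
        if shared_budget[i] > sizes[i]:
            raise ValueError(
                f"set {_set_name(i)}: planted overlaps ({shared_budget[i]}) exceed its size ({sizes[i]})"
            )

    pool = iter(range(spec.universe_size))

    def take(n: int) -> list[str]:
        try:
            return [f"G{next(pool):05d}" for _ in range(n)]
        except StopIteration:
            raise ValueError("universe too small for the requested sets and overlaps") from None

    members: list[set[str]] = [set() for _ in range(k)]
    for (i, j), c in sorted(spec.planted_overlaps.items()):
        genes = take(c)
        members[i].update(genes)
        members[j].update(genes)
    for i in range(k):
        members[i].update(take(sizes[i] - len(members[i])))

    universe = frozenset(f"G{g:05d}" for g in range(spec.universe_size))
    sets = [
        GeneSet(_set_name(i), f"synthetic pathway {i + 1}", frozenset(members[i]))
        for i in range(k)
    ]
    return GeneSetCollection(sets, universe=universe)


def gen_candidate_genes(
    collection: GeneSetCollection,
    true_sets: Sequence[str],
    enrichment_factor: float,
    n_candidates: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample a candidate list enriched in the designated true sets.

    Sampling is without replacement over the universe, with weight
    ``enrichment_factor`` for genes belonging to any true set and 1
    otherwise; factor 1 reproduces the null.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    universe = sorted(collection.universe)
    if n_candidates > len(universe):
        raise ValueError("n_candidates exceeds the universe size")
    favored: set[str] = set()
    for sid in true_sets:
        favored |= collection[sid].members
    weights = np.array([enrichment_factor if g in favored else 1.0 for g in universe])
    weights /= weights.sum()
    picked = rng.choice(len(universe), size=n_candidates, replace=False, p=weights)
    return [universe[i] for i in sorted(picked)]


def gen_host_with_planted_module(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, list[str], list[str]]:
    """Build a host network with seed clusters bridged only by planted linkers.

    Seeds are split into ``n_true_linkers + 1`` cliques arranged in a chain;
    consecutive cliques connect exclusively through one linker node, making
    each linker a cut vertex between its two clusters — every inter-cluster
    seed path must pass through it.  Linkers (never seeds) also attach to a
    background graph drawn from ``host_model``, embedding the module in a
    larger network.  Returns ``(network, seeds, true_linkers)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n_module = spec.n_seeds + spec.n_true_linkers
    n_bg = spec.host_n - n_module
    if n_bg < 1:
        raise ValueError("host_n must exceed n_seeds + n_true_linkers")
    if spec.n_seeds < spec.n_true_linkers + 1:
        raise ValueError("need at least one seed per cluster: n_seeds >= n_true_linkers + 1")

    if spec.host_model == "gnm":
        max_m = n_bg * (n_bg - 1) // 2
        bg = nx.gnm_random_graph(n_bg, min(spec.host_m, max_m), seed=rng)
    elif spec.host_model == "preferential-attachment":
        m_pa = max(1, min(round(spec.host_m / max(n_bg, 1)), n_bg - 1))
        bg = nx.barabasi_albert_graph(n_bg, m_pa, seed=rng)
    else:
        raise ValueError(f"unknown host_model: {spec.host_model!r}")

    g: nx.Graph = nx.Graph()
    bg_names = [f"B{i:04d}" for i in range(n_bg)]
    g.add_nodes_from(bg_names)
    g.add_edges_from((bg_names[u], bg_names[v]) for u, v in bg.edges())

    seeds = [f"S{i:03d}" for i in range(spec.n_seeds)]
    linkers = [f"L{i:02d}" for i in range(spec.n_true_linkers)]
    clusters = [[str(s) for s in c] for c in np.array_split(seeds, spec.n_true_linkers + 1)]
    for cluster in clusters:
        for a_i in range(len(cluster)):
            for b_i in range(a_i + 1, len(cluster)):
                g.add_edge(cluster[a_i], cluster[b_i])
        g.add_nodes_from(cluster)
    # chain: cluster_i — L_i — cluster_{i+1}; seeds touch nothing else
    for i, linker in enumerate(linkers):
        for s in clusters[i]:
            g.add_edge(linker, s)
        for s in clusters[i + 1]:
            g.add_edge(linker, s)
    if linkers:
        # the module hangs off the background through a single anchor, so
        # every linker stays a cut vertex between its two seed clusters
        anchor = bg_names[int(rng.integers(n_bg))]
        g.add_edge(linkers[0], anchor)
    else:
        # a single seed clique has nothing to bypass; anchor it directly
        anchor = bg_names[int(rng.integers(n_bg))]
        g.add_edge(seeds[0], anchor)
    return g, seeds, linkers


def write_synthetic_inputs(
    spec: SyntheticSpec,
    outdir: str | Path,
) -> dict[str, Path]:
    """Materialize one synthetic study as GMT / gene-list / edge-list files.

    Writes ``collection.gmt``, ``candidates.txt``, ``network.tsv``,
    ``seeds.txt`` and ``true_linkers.txt`` under ``outdir`` and returns their
    paths, letting the full command-line pipeline run end-to-end offline.

    Host nodes are relabeled into universe gene identifiers so the files are
    mutually consistent the way real inputs are: the planted seeds become the
    first ``n_seeds`` candidate genes, linkers and background nodes become
    non-candidate genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    collection = gen_pathway_collection(spec)
    candidates = gen_candidate_genes(
        collection, spec.true_sets, spec.enrichment_factor, spec.n_candidates, rng
    )
    network, seeds, true_linkers = gen_host_with_planted_module(spec, rng)

    if spec.n_seeds > len(candidates):
        raise ValueError("n_seeds exceeds n_candidates")
    non_candidates = sorted(collection.universe - set(candidates))
    n_other = network.number_of_nodes() - spec.n_seeds
    if n_other > len(non_candidates):
        raise ValueError("universe too small to label all host nodes")
    relabel = dict(zip(seeds, candidates[: spec.n_seeds]))
    others = sorted(set(network.nodes) - set(seeds))
    relabel.update(zip(others, non_candidates[:n_other]))
    network = nx.relabel_nodes(network, relabel)
    seeds = [relabel[s] for s in seeds]
    true_linkers = [relabel[l] for l in true_linkers]

    paths = {
        "collection": outdir / "collection.gmt",
        "candidates": outdir / "candidates.txt",
        "universe": outdir / "universe.txt",
        "network": outdir / "network.tsv",
        "seeds": outdir / "seeds.txt",
        "true_linkers": outdir / "true_linkers.txt",
    }
    write_gmt(collection, paths["collection"])
    paths["universe"].write_text("\n".join(sorted(collection.universe)) + "\n",
                                 encoding="utf-8")
    paths["candidates"].write_text("\n".join(candidates) + "\n", encoding="utf-8")
    write_edge_list(network, paths["network"])
    paths["seeds"].write_text("\n".join(seeds) + "\n", encoding="utf-8")
    paths["true_linkers"].write_text(
        "\n".join(true_linkers) + ("\n" if true_linkers else ""), encoding="utf-8"
    )
    return paths
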