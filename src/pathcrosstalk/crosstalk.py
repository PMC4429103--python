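"""Pathway-crosstalk graph: overlap scoring, edge filtering and top-fraction selection.

Two pathways crosstalk when they share enough candidate genes.  The overlap
of candidate-hit sets A and B is scored by the Jaccard coefficient
JC = |A∩B| / |A∪B| and the overlap coefficient OC = |A∩B| / min(|A|, |B|);
the edge score is their arithmetic mean.  Since JC <= OC always, the score
lies between the two.  Scoring uses the candidate genes hitting each pathway
(not full pathway membership): the crosstalk of interest is between the
disease-relevant portions of the pathways.

The selection cascade is: keep pathways with >= 5 candidate hits and
BH-adjusted p < 0.01 (done upstream by ``enrichment.filter_results``), keep
pairs sharing >= 3 candidate genes, rank by score, keep the top 20%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkEdge",
    "CrosstalkGraph",
    "jaccard",
    "overlap_coefficient",
    "build_crosstalk",
    "select_top_fraction",
    "write_edge_table",
]


def jaccard(A: Iterable[str], B: Iterable[str]) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; 0 when both sets are empty."""
    a, b = set(A), set(B)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_coefficient(A: Iterable[str], B: Iterable[str]) -> float:
    """Overlap (Szymkiewicz–Simpson) coefficient |A∩B| / min(|A|, |B|)."""
    a, b = set(A), set(B)
    denom = min(len(a), len(b))
    if denom == 0:
        raise ValueError("overlap coefficient undefined when a set is empty")
    return len(a & b) / denom


@dataclass(frozen=True)
class CrosstalkEdge:
    """One scored pathway pair; ``set_a < set_b`` lexicographically."""

    set_a: str
    set_b: str
    shared: frozenset[str]
    jc: float
    oc: float
    score: float

    def __post_init__(self) -> None:
        if self.set_a >= self.set_b:
            raise ValueError("edge endpoints must satisfy set_a < set_b")
        if not self.shared:
            raise ValueError("crosstalk edge with no shared genes")
        if self.jc > self.oc + 1e-12:
            raise ValueError("jc cannot exceed oc")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.set_a, self.set_b)


@dataclass
class CrosstalkGraph:
    """Pathway nodes (with hit counts and adjusted p) plus scored crosstalk edges."""

    nodes: dict[str, EnrichmentResult]
    edges: list[CrosstalkEdge]

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate pathway pairs")
        for e in self.edges:
            if e.set_a not in self.nodes or e.set_b not in self.nodes:
                raise ValueError(f"edge endpoint missing from nodes: {e.pair}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for set_id, r in self.nodes.items():
            g.add_node(set_id, k=r.k, p_bh=r.p_bh)
        for e in self.edges:
            g.add_edge(e.set_a, e.set_b, score=e.score, jc=e.jc, oc=e.oc,
                       n_shared=len(e.shared))
        return g


def build_crosstalk(
    filtered: Sequence[EnrichmentResult],
    min_shared: int = 3,
) -> CrosstalkGraph:
    """Score all pathway pairs and keep those sharing >= ``min_shared`` candidate genes.

    ``filtered`` must already have passed the per-pathway filters; scoring is
    on ``members_hit``.  Pathways left without any retained partner are
    dropped from the node set.  Edges come back sorted by score descending,
    ties broken by the (set_a, set_b) pair.
    """
    if len(filtered) < 2:
        raise ValueError("crosstalk needs at least two pathways")
    by_id = {r.set_id: r for r in filtered}
    if len(by_id) != len(filtered):
        raise ValueError("duplicate set ids in filtered results")

    edges: list[CrosstalkEdge] = []
    for ra, rb in combinations(sorted(filtered, key=lambda r: r.set_id), 2):
        shared = ra.members_hit & rb.members_hit
        if len(shared) < min_shared:
            continue
        a, b = sorted((ra.set_id, rb.set_id))
        jc = jaccard(ra.members_hit, rb.members_hit)
        oc = overlap_coefficient(ra.members_hit, rb.members_hit)
        edges.append(CrosstalkEdge(a, b, frozenset(shared), jc, oc, (jc + oc) / 2.0))

    edges.sort(key=lambda e: (-e.score, e.set_a, e.set_b))
    participating = {s for e in edges for s in e.pair}
    nodes = {sid: by_id[sid] for sid in sorted(participating)}
    return CrosstalkGraph(nodes=nodes, edges=edges)


def select_top_fraction(graph: CrosstalkGraph, fraction: float = 0.20) -> CrosstalkGraph:
    """Keep the ceil(fraction * |edges|) highest-scoring edges, ties at the cut included.

    Equal scores are never split: if the edge at the cut ties with edges just
    below it, all of them are kept and the expansion is logged.  Nodes left
    without an edge are dropped.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not graph.edges:
        raise ValueError("no edges to select from")
    n_keep = math.ceil(fraction * len(graph.edges))
    threshold = graph.edges[n_keep - 1].score
    kept = [e for e in graph.edges if e.score >= threshold]
    if len(kept) > n_keep:
        logger.info("top-fraction cut expanded from %d to %d edges by score ties at %.6g",
                    n_keep, len(kept), threshold)
    participating = {s for e in kept for s in e.pair}
    nodes = {sid: graph.nodes[sid] for sid in sorted(participating)}
    return CrosstalkGraph(nodes=nodes, edges=kept)


def write_edge_table(graph: CrosstalkGraph, path: str | Path) -> None:
    """Write the scored edges as a tab-separated table (shared genes comma-joined)."""
    df = pd.DataFrame(
        {
            "set_a": [e.set_a for e in graph.edges],
            "set_b": [e.set_b for e in graph.edges],
            "n_shared": [len(e.shared) for e in graph.edges],
            "jc": [e.jc for e in graph.edges],
            "oc": [e.oc for e in graph.edges],
            "score": [e.score for e in graph.edges],
            "shared_genes": [",".join(sorted(e.shared)) for e in graph.edges],
        }
    )
    df.to_csv(path, sep="\t", index=False)
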