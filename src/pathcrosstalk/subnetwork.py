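"""Seed-spanning subnetwork extraction by a greedy Steiner minimal-tree heuristic.

Starting from one singleton tree per seed present in the host network, the
two trees at minimal host shortest-path distance (unit edge lengths) are
repeatedly merged along that shortest path; interior path nodes enter the
solution as *linkers* — non-seed genes recruited to connect the seeds.
Merging stops when a single tree remains per connected component (a Steiner
forest when the host is disconnected).  The reported subnetwork is the host
subgraph *induced* on the final node set, so it generally carries more edges
than the tree itself.

Because the globally closest pair is always merged first, a connecting path
can never run through a third tree's interior (that tree would be strictly
closer), so the union of merges stays acyclic.  All tie-breaking is
lexicographic, making results deterministic.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "SteinerResult",
    "TopologyStats",
    "steiner_tree_greedy",
    "steiner_brute_force",
    "topology_stats",
]


@dataclass
class SteinerResult:
    """Outcome of greedy Steiner extraction.

    ``tree_edges`` form a forest whose leaves are all seeds; ``subnetwork``
    is the host-induced subgraph on ``node_set`` (a superset of the tree).
    """

    tree_edges: frozenset[tuple[str, str]]
    node_set: frozenset[str]
    seeds_in: frozenset[str]
    seeds_dropped: frozenset[str]
    linkers: frozenset[str]
    subnetwork: nx.Graph


def _multi_source_bfs(adj: dict[str, list[str]], sources: Sequence[str]):
    """BFS from a sorted source set; returns dist, parent and BFS-root maps.

    Sources are enqueued in sorted order and neighbors visited in sorted
    order, so the shortest path recovered for any target is deterministic.
    """
    dist: dict[str, int] = {}
    parent: dict[str, str | None] = {}
    root: dict[str, str] = {}
    q: deque[str] = deque()
    for s in sorted(sources):
        dist[s] = 0
        parent[s] = None
        root[s] = s
        q.append(s)
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                root[v] = root[u]
                q.append(v)
    return dist, parent, root


def _path_to(target: str, parent: dict[str, str | None]) -> list[str]:
    path = [target]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])  # type: ignore[arg-type]
    path.reverse()
    return path


def steiner_tree_greedy(network: nx.Graph, seeds: Iterable[str]) -> SteinerResult:
    """Connect the seeds present in ``network`` by greedy shortest-path tree merging.

    Seeds absent from the host are reported in ``seeds_dropped``; seeds split
    across host components yield a Steiner forest with a logged warning.
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("no seeds given")
    present = seed_set & set(network.nodes)
    dropped = seed_set - present
    if not present:
        raise ValueError("no seed is present in the host network")
    if dropped:
        logger.warning("%d seeds absent from the host network", len(dropped))

    # sorted adjacency once, for deterministic BFS order
    adj = {u: sorted(network.neighbors(u)) for u in network.nodes}

    components = [c for c in nx.connected_components(network) if c & present]
    if len(components) > 1:
        logger.warning("seeds span %d host components; returning a Steiner forest",
                       len(components))

    tree_edges: set[tuple[str, str]] = set()
    node_set: set[str] = set()
    for comp in sorted(components, key=min):
        comp_seeds = sorted(comp & present)
        trees: list[set[str]] = [{s} for s in comp_seeds]
        bfs = [_multi_source_bfs(adj, sorted(t)) for t in trees]
        while len(trees) > 1:
            best_key = None
            best = None  # (i, j, path)
            for i, j in combinations(range(len(trees)), 2):
                # measure from the tree whose smallest node is smaller: the
                # symmetric distance is identical, the recovered path fixed
                src, dst = (i, j) if min(trees[i]) <= min(trees[j]) else (j, i)
                dist, parent, root = bfs[src]
                target = min(trees[dst], key=lambda v: (dist[v], v))
                d = dist[target]
                path = _path_to(target, parent)
                u, v = path[0], path[-1]
                key = (d, min(u, v), max(u, v), path)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j, path)
            assert best is not None
            i, j, path = best
            for a, b in zip(path, path[1:]):
                tree_edges.add(tuple(sorted((a, b))))
            merged = trees[i] | trees[j] | set(path)
            for idx in sorted((i, j), reverse=True):
                del trees[idx]
                del bfs[idx]
            trees.append(merged)
            bfs.append(_multi_source_bfs(adj, sorted(merged)))
        node_set |= trees[0]

    linkers = node_set - present
    sub = network.subgraph(node_set).copy()
    return SteinerResult(
        tree_edges=frozenset(tree_edges),
        node_set=frozenset(node_set),
        seeds_in=frozenset(node_set & present),
        seeds_dropped=frozenset(dropped),
        linkers=frozenset(linkers),
        subnetwork=sub,
    )


def steiner_brute_force(network: nx.Graph, seeds: Iterable[str]) -> nx.Graph:
    """Exact minimum-edge Steiner tree by exhaustive search over linker subsets.

    Only feasible on tiny hosts (<= 15 nodes); used as the testing oracle for
    the greedy heuristic.  In an unweighted graph a tree on V' has |V'| - 1
    edges, so minimizing edges is minimizing recruited nodes: subsets of
    non-seed nodes are enumerated by increasing size and the first subset
    whose induced subgraph connects all seeds wins.
    """
    if network.number_of_nodes() > 15:
        raise ValueError("brute-force Steiner limited to hosts with <= 15 nodes")
    seed_set = set(seeds)
    if not seed_set <= set(network.nodes):
        raise ValueError("all seeds must be present in the host network")
    others = sorted(set(network.nodes) - seed_set)
    for r in range(len(others) + 1):
        for extra in combinations(others, r):
            nodes = seed_set | set(extra)
            sub = network.subgraph(nodes)
            if nx.is_connected(sub):
                tree = nx.bfs_tree(sub, min(nodes)).to_undirected()
                return nx.Graph(tree.edges)
    raise ValueError("seeds are not connected in the host network")


@dataclass(frozen=True)
class TopologyStats:
    """Average shortest-path length (connected pairs only) and mean local clustering."""

    avg_path_len: float
    avg_clustering: float


def topology_stats(network: nx.Graph) -> TopologyStats:
    """Topology statistics used by the randomization test.

    The path length averages d(u, v) over all unordered *connected* node
    pairs, which stays well defined on disconnected graphs.  The clustering
    coefficient averages the local coefficient over all nodes, with degree
    < 2 nodes contributing 0.
    """
    if network.number_of_nodes() < 2:
        raise ValueError("topology statistics need at least two nodes")
    if network.number_of_edges() == 0:
        raise ValueError("average path length undefined on an edgeless network")
    total = 0
    n_pairs = 0
    for u, dists in nx.all_pairs_shortest_path_length(network):
        for v, d in dists.items():
            if u < v:
                total += d
                n_pairs += 1
    return TopologyStats(
        avg_path_len=total / n_pairs,
        avg_clustering=nx.average_clustering(network, count_zeros=True),
    )
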