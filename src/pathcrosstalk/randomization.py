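"""Significance of subnetwork topology against Erdős–Rényi G(n, m) null graphs.

The observed subnetwork is compared with an ensemble of uniform random
simple graphs matched on node and edge counts.  Two statistics are tested:
the average shortest-path distance L (a small L means the network is more
tightly knit than chance) and the average clustering coefficient C (a large
C means more local triangle structure than chance).  Empirical p-values are
the fraction of null graphs strictly beating the observed value:
p_L = #(L_null < L_obs) / reps and p_C = #(C_null > C_obs) / reps.

G(n, m) at realistic subnetwork densities is frequently disconnected; the
connected-pairs convention of :func:`~pathcrosstalk.subnetwork.topology_stats`
keeps L finite in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .subnetwork import TopologyStats, topology_stats

__all__ = ["NullEnsemble", "RandomizationResult", "er_gnm", "null_test",
           "write_randomization_report"]


def er_gnm(n: int, m: int, rng: np.random.Generator) -> nx.Graph:
    """Draw a uniform simple graph with exactly n nodes and m edges."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m={m} outside [0, {max_m}] for n={n}")
    g = nx.gnm_random_graph(n, m, seed=rng)
    assert g.number_of_nodes() == n and g.number_of_edges() == m
    return g


@dataclass
class NullEnsemble:
    """Per-replicate null statistics for a G(n, m) ensemble."""

    reps: int
    path_len_samples: list[float]
    clustering_samples: list[float]
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.path_len_samples) != self.reps or len(self.clustering_samples) != self.reps:
            raise ValueError("sample lists must have length reps")


@dataclass
class RandomizationResult:
    """Observed statistics, null counts and empirical p-values."""

    n: int
    m: int
    observed: TopologyStats
    ensemble: NullEnsemble
    n_L: int
    n_C: int

    @property
    def p_L(self) -> float:
        return self.n_L / self.ensemble.reps

    @property
    def p_C(self) -> float:
        return self.n_C / self.ensemble.reps

    def _fmt_p(self, p: float) -> str:
        return f"0 (< {1 / self.ensemble.reps:g})" if p == 0.0 else f"{p:g}"

    @property
    def p_L_str(self) -> str:
        return self._fmt_p(self.p_L)

    @property
    def p_C_str(self) -> str:
        return self._fmt_p(self.p_C)


def null_test(
    observed_network: nx.Graph,
    reps: int = 1000,
    seed: int | None = None,
) -> RandomizationResult:
    """Test the observed network against ``reps`` size-matched G(n, m) draws.

    Strict inequalities: a null replicate equal to the observed value does
    not count as beating it.  Replicates use deterministic substreams spawned
    from the master seed, so results are bit-reproducible given
    (n, m, reps, seed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = observed_network.number_of_nodes()
    m = observed_network.number_of_edges()
    obs = topology_stats(observed_network)

    children = np.random.SeedSequence(seed).spawn(reps)
    L_samples: list[float] = []
    C_samples: list[float] = []
    for child in children:
        g = er_gnm(n, m, np.random.default_rng(child))
        stats = topology_stats(g)
        L_samples.append(stats.avg_path_len)
        C_samples.append(stats.avg_clustering)

    n_L = sum(1 for L in L_samples if L < obs.avg_path_len)
    n_C = sum(1 for C in C_samples if C > obs.avg_clustering)
    ensemble = NullEnsemble(reps=reps, path_len_samples=L_samples,
                            clustering_samples=C_samples, seed=seed)
    return RandomizationResult(n=n, m=m, observed=obs, ensemble=ensemble,
                               n_L=n_L, n_C=n_C)


def write_randomization_report(result: RandomizationResult, path: str | Path) -> None:
    """Write a one-row tab-separated report of the randomization test."""
    L = np.asarray(result.ensemble.path_len_samples)
    C = np.asarray(result.ensemble.clustering_samples)
    header = ["n", "m", "reps", "seed", "observed_L", "observed_C",
              "null_L_mean", "null_L_sd", "null_C_mean", "null_C_sd",
              "n_L", "n_C", "p_L", "p_C"]
    row = [result.n, result.m, result.ensemble.reps, result.ensemble.seed,
           f"{result.observed.avg_path_len:.6g}", f"{result.observed.avg_clustering:.6g}",
           f"{L.mean():.6g}", f"{L.std(ddof=1):.6g}" if result.ensemble.reps > 1 else "nan",
           f"{C.mean():.6g}", f"{C.std(ddof=1):.6g}" if result.ensemble.reps > 1 else "nan",
           result.n_L, result.n_C, result.p_L_str, result.p_C_str]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        fh.write("\t".join(str(x) for x in row) + "\n")
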