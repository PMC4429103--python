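"""Gene-set overlap enrichment with Benjamini–Hochberg correction.

The test is the one-sided hypergeometric upper tail: for a universe of N
genes of which K belong to a set, and n candidate genes of which k fall in
the set, the p-value is P(X >= k) for X ~ Hypergeometric(N, K, n).  This is
identical to the one-sided Fisher's exact test on the corresponding 2x2
table.  Only enrichment (upper tail) is tested, never depletion.

The BH family is, by default, the sets with at least one candidate hit —
mirroring tools that first extract overlapping sets and then correct across
exactly those — and can be widened to the whole collection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "bh_adjust",
    "enrich",
    "filter_results",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts and p-values for one gene set.

    k  : candidate genes in the set (within the universe)
    K  : set size within the universe
    n  : candidate genes within the universe
    N  : universe size
    """

    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    members_hit: frozenset[str]
    p_raw: float
    p_bh: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"{self.set_id}: inconsistent counts k={self.k}, K={self.K}, n={self.n}")
        if len(self.members_hit) != self.k:
            raise ValueError(f"{self.set_id}: members_hit has {len(self.members_hit)} genes, k={self.k}")
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_bh <= 1.0):
            raise ValueError(f"{self.set_id}: p-values outside [0, 1]")


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Equals the one-sided Fisher's exact p for the 2x2 table
    [[k, K-k], [n-k, N-K-n+k]].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    Sorted p_(i) is multiplied by m/i, a running minimum is taken from the
    largest rank down, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


def enrich(
    candidates: Iterable[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str] | None = None,
    bh_family: str = "extracted",
) -> list[EnrichmentResult]:
    """Test every gene set for enrichment in the candidate list.

    Candidates outside the universe are excluded from the test (their count
    is logged); sets with zero overlap are not reported.  BH correction is
    applied across the reported sets (``bh_family="extracted"``, default) or
    across the whole collection (``"all"``).  Results are sorted by raw
    p-value, ties broken by set id.
    """
    if bh_family not in ("extracted", "all"):
        raise ValueError(f"unknown bh_family: {bh_family!r}")
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("empty universe")
    cand = list(dict.fromkeys(candidates))
    effective = [g for g in cand if g in uni]
    n_lost = len(cand) - len(effective)
    if n_lost:
        logger.warning("%d of %d candidate genes are outside the universe and were excluded",
                       n_lost, len(cand))
    if not effective:
        raise ValueError("no candidate genes fall inside the universe")
    cand_set = frozenset(effective)
    n, N = len(cand_set), len(uni)

    rows = []
    for s in collection:
        members = s.members & uni
        hit = members & cand_set
        if not hit:
            continue
        p = hypergeometric_pvalue(len(hit), len(members), n, N)
        rows.append((s, hit, len(members), p))

    if not rows:
        raise ValueError("no gene set overlaps the candidate list")

    if bh_family == "extracted":
        adj = bh_adjust([r[3] for r in rows])
    else:
        m_all = len(collection)
        # sets with k = 0 enter the family with p = 1
        padded = [r[3] for r in rows] + [1.0] * (m_all - len(rows))
        adj = bh_adjust(padded)[: len(rows)]

    results = [
        EnrichmentResult(
            set_id=s.set_id,
            description=s.description,
            k=len(hit),
            K=K,
            n=n,
            N=N,
            members_hit=frozenset(hit),
            p_raw=p,
            p_bh=p_adj,
        )
        for (s, hit, K, p), p_adj in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.set_id))
    return results


def filter_results(
    results: Sequence[EnrichmentResult],
    min_genes: int = 5,
    max_p_bh: float = 0.01,
    min_depth: int | None = None,
    depth_map: Mapping[str, int] | None = None,
) -> list[EnrichmentResult]:
    """Apply the reporting filters: k >= min_genes, p_bh strictly < max_p_bh,
    and optionally a minimum hierarchy depth from a precomputed depth table.

    Order is preserved.  Sets with fewer candidate hits than ``min_genes``
    carry too little signal for overlap scoring and are dropped.
    """
    kept = []
    for r in results:
        if r.k < min_genes or not r.p_bh < max_p_bh:
            continue
        if min_depth is not None:
            if depth_map is None or r.set_id not in depth_map:
                raise ValueError(f"no hierarchy depth available for set {r.set_id!r}")
            if depth_map[r.set_id] < min_depth:
                continue
        kept.append(r)
    return kept


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write results as a tab-separated table (members comma-joined)."""
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "description": [r.description for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bh": [r.p_bh for r in results],
            "members_hit": [",".join(sorted(r.members_hit)) for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
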