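"""Readers and writers for gene lists, gene-set collections and interaction networks.

Identifiers are plain strings (gene symbols, or numeric ids rendered as text)
passed through a single normalization step — by default uppercasing, which is
how symbol-keyed gene sets are usually matched.  Networks are undirected
simple graphs held in :class:`networkx.Graph`; the cleaning rules applied on
read (drop self-interactions, collapse redundant pairs regardless of
orientation) are the standard preparation of a protein–protein interaction
edge list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "normalize_gene_id",
    "read_mapping",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_sif",
    "write_edge_list",
    "write_node_attributes",
    "write_graphml",
]


def normalize_gene_id(
    symbol: str,
    case: str = "upper",
    mapping: Mapping[str, str] | None = None,
) -> str:
    """Normalize one identifier: trim, fold case, then apply an optional mapping.

    ``case`` is one of ``"upper"`` (default), ``"lower"`` or ``"none"``.  The
    mapping (e.g. accession → symbol) is applied after case folding and its
    output is returned verbatim.
    """
    token = symbol.strip()
    if not token:
        raise ValueError("empty gene identifier")
    if case == "upper":
        token = token.upper()
    elif case == "lower":
        token = token.lower()
    elif case != "none":
        raise ValueError(f"unknown case policy: {case!r}")
    if mapping is not None:
        token = mapping.get(token, token)
    return token


def read_mapping(path: str | Path, case: str = "upper") -> dict[str, str]:
    """Read a two-column identifier mapping file (from-id <tab/space> to-id)."""
    out: dict[str, str] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        out[normalize_gene_id(fields[0], case)] = normalize_gene_id(fields[1], case="none")
    return out


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (pathway) with a non-empty member set."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets plus a background universe.

    When ``universe`` is not given it defaults to the union of all member
    genes, the usual fallback when the annotation source does not publish its
    background.
    """

    sets: list[GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set ids: {dup}")
        members = frozenset().union(*(s.members for s in self.sets)) if self.sets else frozenset()
        if not self.universe:
            self.universe = members
        elif not members <= self.universe:
            raise ValueError("explicit universe does not cover all set members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


def _data_rows(path: str | Path):
    """Yield (lineno, whitespace-or-tab split fields), skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            yield lineno, [f.strip() for f in fields]


def read_gene_list(
    path: str | Path,
    case: str = "upper",
    mapping: Mapping[str, str] | None = None,
) -> list[str]:
    """Read a one-identifier-per-line gene list.

    Order is preserved; duplicates (after normalization) collapse to their
    first occurrence with a logged warning; blank lines and ``#`` comments are
    ignored.  An empty result raises, because an empty candidate list makes
    every downstream step meaningless.
    """
    seen: dict[str, None] = {}
    n_dup = 0
    for lineno, fields in _data_rows(path):
        gene = normalize_gene_id(fields[0], case, mapping)
        if gene in seen:
            n_dup += 1
            logger.warning("%s:%d: duplicate gene %s collapsed", path, lineno, gene)
        else:
            seen[gene] = None
    if not seen:
        raise ValueError(f"{path}: no usable gene identifiers found")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate identifiers", path, n_dup)
    return list(seen)


def read_gmt(
    path: str | Path,
    case: str = "upper",
    mapping: Mapping[str, str] | None = None,
) -> GeneSetCollection:
    """Read a GMT gene-set file (name <tab> description <tab> gene ...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, description, >=1 gene)"
                )
            name, description = fields[0].strip(), fields[1].strip()
            members = frozenset(
                normalize_gene_id(g, case, mapping) for g in fields[2:] if g.strip()
            )
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, description, members))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def read_network(
    path: str | Path,
    case: str = "upper",
    mapping: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a two-column edge list (or MITAB-style pair file) into a clean graph.

    The first two fields of each data row are the endpoints; extra columns are
    ignored so MITAB exports work unmodified.  Self-interactions are dropped
    and redundant pairs — repeats in either orientation — are stored once;
    both counts are logged.
    """
    g: nx.Graph = nx.Graph()
    n_rows = n_self = n_dup = 0
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least two columns")
        u = normalize_gene_id(fields[0], case, mapping)
        v = normalize_gene_id(fields[1], case, mapping)
        n_rows += 1
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no valid edges after cleaning ({n_rows} rows read)")
    logger.info(
        "%s: %d rows -> %d nodes, %d edges (%d self-interactions, %d redundant pairs dropped)",
        path, n_rows, g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
    )
    return g


def write_sif(network: nx.Graph, path: str | Path, interaction: str = "interacts") -> None:
    """Write a Cytoscape SIF file, one edge per row, endpoints in lexicographic order."""
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    rows = sorted(tuple(sorted((str(u), str(v)))) for u, v in network.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in rows:
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write a plain two-column edge list (readable back by :func:`read_network`)."""
    rows = sorted(tuple(sorted((str(u), str(v)))) for u, v in network.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def write_node_attributes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated node attribute table with a header row."""
    table.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def write_graphml(
    network: nx.Graph,
    path: str | Path,
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
    edge_attributes: Mapping[tuple[str, str], Mapping[str, object]] | None = None,
) -> None:
    """Write GraphML with optional per-node / per-edge attribute dictionaries.

    ``node_attributes`` maps attribute name → {node: value}; ``edge_attributes``
    maps (u, v) → {attribute: value}.
    """
    g = network.copy()
    if node_attributes:
        for attr, values in node_attributes.items():
            nx.set_node_attributes(g, dict(values), attr)
    if edge_attributes:
        for (u, v), attrs in edge_attributes.items():
            if g.has_edge(u, v):
                g.edges[u, v].update(attrs)
    nx.write_graphml(g, path)
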