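"""End-to-end orchestration: enrich → filter → crosstalk → subnetwork → null test.

The pipeline is configured by a :class:`PipelineConfig` whose threshold
defaults are the canonical ones for this analysis: BH-adjusted p < 0.01 and
>= 5 candidate hits per pathway, >= 3 shared candidate genes per pathway
pair, top 20% of crosstalk scores, and 1000 null replicates.  A flat
``key=value`` config file can populate it; command-line flags override.

Every run writes a manifest recording the package version, seed, thresholds
and SHA-256 checksums of all inputs and outputs, so a run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .crosstalk import build_crosstalk, select_top_fraction, write_edge_table
from .enrichment import enrich, filter_results, write_enrichment_table
from .io import (read_gene_list, read_gmt, read_network, write_graphml,
                 write_node_attributes, write_sif)
from .randomization import null_test, write_randomization_report
from .subnetwork import steiner_tree_greedy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "parse_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    candidates: str = ""
    collection: str = ""
    network: str = ""
    universe: str = ""          # optional explicit background gene list
    max_p_bh: float = 0.01
    min_genes: int = 5
    min_shared: int = 3
    top_fraction: float = 0.20
    reps: int = 1000
    rng_seed: int = 0
    outdir: str = "pathcrosstalk_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_p_bh <= 1.0:
            raise ValueError("max_p_bh must be in (0, 1]")
        if self.min_genes < 1 or self.min_shared < 1 or self.reps < 1:
            raise ValueError("min_genes, min_shared and reps must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def parse_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat key=value config file; keyword overrides take precedence."""
    values: dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = raw
    values.update({k: v for k, v in overrides.items() if v is not None})
    coerced: dict[str, object] = {}
    for key, raw in values.items():
        kind = _FIELD_TYPES[key]
        if isinstance(raw, str) and kind in ("int", "float"):
            raw = int(raw) if kind == "int" else float(raw)
        coerced[key] = raw
    return PipelineConfig(**coerced)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all tables, exports and a manifest.

    Returns the manifest dictionary.  Stage failures are re-raised with the
    stage name attached; the manifest's ``completed_stages`` records how far
    the run got.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pathcrosstalk",
        "version": __version__,
        "seed": config.rng_seed,
        "thresholds": {
            "max_p_bh": config.max_p_bh,
            "min_genes": config.min_genes,
            "min_shared": config.min_shared,
            "top_fraction": config.top_fraction,
            "reps": config.reps,
        },
        "inputs": {},
        "outputs": {},
        "completed_stages": [],
    }
    for name in ("candidates", "collection", "network", "universe"):
        value = getattr(config, name)
        if value:
            manifest["inputs"][name] = {"path": value, "sha256": _sha256(Path(value))}

    stage = "load"
    try:
        candidates = read_gene_list(config.candidates)
        collection = read_gmt(config.collection)
        universe = frozenset(read_gene_list(config.universe)) if config.universe else None
        network = read_network(config.network)
        manifest["completed_stages"].append(stage)

        stage = "enrich"
        results = enrich(candidates, collection, universe=universe)
        write_enrichment_table(results, outdir / "enrichment.tsv")
        filtered = filter_results(results, min_genes=config.min_genes,
                                  max_p_bh=config.max_p_bh)
        write_enrichment_table(filtered, outdir / "enrichment_filtered.tsv")
        manifest["completed_stages"].append(stage)

        stage = "crosstalk"
        graph = build_crosstalk(filtered, min_shared=config.min_shared)
        write_edge_table(graph, outdir / "crosstalk_edges.tsv")
        top = select_top_fraction(graph, fraction=config.top_fraction)
        write_edge_table(top, outdir / "crosstalk_top.tsv")
        g = top.to_networkx()
        write_sif(g, outdir / "crosstalk_top.sif", interaction="crosstalk")
        write_graphml(g, outdir / "crosstalk_top.graphml")
        pathway_attrs = pd.DataFrame(
            {
                "set_id": list(top.nodes),
                "k": [r.k for r in top.nodes.values()],
                "p_bh": [r.p_bh for r in top.nodes.values()],
            }
        )
        write_node_attributes(pathway_attrs, outdir / "crosstalk_top_nodes.tsv")
        manifest["completed_stages"].append(stage)

        stage = "subnetwork"
        steiner = steiner_tree_greedy(network, candidates)
        write_sif(steiner.subnetwork, outdir / "subnetwork.sif")
        write_graphml(
            steiner.subnetwork,
            outdir / "subnetwork.graphml",
            node_attributes={
                "role": {v: ("seed" if v in steiner.seeds_in else "linker")
                         for v in steiner.node_set},
                "host_degree": {v: network.degree(v) for v in steiner.node_set},
            },
        )
        node_attrs = pd.DataFrame(
            {
                "gene": sorted(steiner.node_set),
                "role": [("seed" if v in steiner.seeds_in else "linker")
                         for v in sorted(steiner.node_set)],
                "host_degree": [network.degree(v) for v in sorted(steiner.node_set)],
            }
        )
        write_node_attributes(node_attrs, outdir / "subnetwork_nodes.tsv")
        manifest["completed_stages"].append(stage)

        stage = "nulltest"
        rand = null_test(steiner.subnetwork, reps=config.reps, seed=config.rng_seed)
        write_randomization_report(rand, outdir / "randomization.tsv")
        manifest["completed_stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["summary"] = {
        "n_candidates": len(candidates),
        "n_sets_tested": len(results),
        "n_sets_filtered": len(filtered),
        "n_crosstalk_edges": len(graph.edges),
        "n_crosstalk_edges_top": len(top.edges),
        "subnetwork_nodes": steiner.subnetwork.number_of_nodes(),
        "subnetwork_edges": steiner.subnetwork.number_of_edges(),
        "seeds_in": len(steiner.seeds_in),
        "linkers": len(steiner.linkers),
        "observed_L": rand.observed.avg_path_len,
        "observed_C": rand.observed.avg_clustering,
        "n_L": rand.n_L,
        "n_C": rand.n_C,
        "p_L": rand.p_L_str,
        "p_C": rand.p_C_str,
    }
    for out in sorted(outdir.iterdir()):
        if out.name != "manifest.json":
            manifest["outputs"][out.name] = {"sha256": _sha256(out)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
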