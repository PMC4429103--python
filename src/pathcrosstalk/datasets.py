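"""Bundled reference data.

One dataset ships with the package: the 20 canonical pathways most strongly
enriched in a published list of 220 nicotine-addiction candidate genes,
together with the candidate genes each pathway contains.  The gene lists are
candidate *hits* (the members of the candidate list falling in the pathway),
which is exactly the input the crosstalk stage scores, so this dataset
doubles as a worked example for the whole crosstalk cascade.

One printed list contains a run-together token ("DRD3GRIN3A"); it is stored
here as the two separate genes.
"""

from __future__ import annotations

from importlib import resources

from .enrichment import EnrichmentResult
from .io import GeneSetCollection, read_gmt

__all__ = ["load_na_pathways", "na_pathway_hits_as_results"]


def load_na_pathways() -> GeneSetCollection:
    """Load the bundled nicotine-addiction pathway collection (20 sets)."""
    ref = resources.files("pathcrosstalk") / "data" / "na_enriched_pathways.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)


def na_pathway_hits_as_results() -> list[EnrichmentResult]:
    """Recast the bundled pathway hits as enrichment results for crosstalk input.

    The stored gene lists already are candidate hits, so ``members_hit`` is
    the full stored membership and ``k = K``.  The published BH-adjusted
    p-value is parsed from the description; the raw p, unrecoverable without
    the original background, is set equal to it (both are far below every
    filtering threshold used here).
    """
    collection = load_na_pathways()
    n = len(collection.universe)
    results = []
    for s in collection:
        p_bh = float(s.description.removeprefix("PBH="))
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                description=s.description,
                k=len(s.members),
                K=len(s.members),
                n=n,
                N=n,
                members_hit=s.members,
                p_raw=p_bh,
                p_bh=p_bh,
            )
        )
    return results
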