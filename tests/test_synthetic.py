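"""Synthetic generators: exact planting, determinism and ground-truth recovery."""

import networkx as nx
import numpy as np
import pytest

from pathcrosstalk.crosstalk import build_crosstalk, jaccard, overlap_coefficient
from pathcrosstalk.enrichment import EnrichmentResult
from pathcrosstalk.subnetwork import steiner_tree_greedy
from pathcrosstalk.synthetic import (SyntheticSpec, gen_candidate_genes,
                                     gen_host_with_planted_module,
                                     gen_pathway_collection,
                                     write_synthetic_inputs)


def hits_as_results(collection):
    """Treat full membership as candidate hits (candidates = whole universe)."""
    n = len(collection.universe)
    return [EnrichmentResult(set_id=s.set_id, description="", k=len(s.members),
                             K=len(s.members), n=n, N=n, members_hit=s.members,
                             p_raw=1e-9, p_bh=1e-8)
            for s in collection]


class TestPathwayCollection:
    def test_planted_pair_reproduces_published_coefficients(self):
        spec = SyntheticSpec(universe_size=1000, set_sizes=(25, 25),
                             planted_overlaps={(0, 1): 24})
        coll = gen_pathway_collection(spec)
        a, b = coll["PW1"].members, coll["PW2"].members
        assert jaccard(a, b) == pytest.approx(24 / 26)
        assert overlap_coefficient(a, b) == pytest.approx(24 / 25)

    def test_zero_overlap(self):
        spec = SyntheticSpec(set_sizes=(10, 10), planted_overlaps={(0, 1): 0})
        coll = gen_pathway_collection(spec)
        assert jaccard(coll["PW1"].members, coll["PW2"].members) == 0.0

    def test_threshold_forced_edge_count(self):
        spec = SyntheticSpec(set_sizes=(10, 10, 10),
                             planted_overlaps={(0, 1): 3, (1, 2): 3, (0, 2): 0})
        coll = gen_pathway_collection(spec)
        graph = build_crosstalk(hits_as_results(coll), min_shared=3)
        assert len(graph.edges) == 2

    def test_all_pairwise_overlaps_exact(self):
        spec = SyntheticSpec(set_sizes=(30, 25, 20, 15),
                             planted_overlaps={(0, 1): 7, (0, 2): 3, (1, 3): 5, (2, 3): 0})
        coll = gen_pathway_collection(spec)
        members = {s.set_id: s.members for s in coll}
        expect = {("PW1", "PW2"): 7, ("PW1", "PW3"): 3, ("PW2", "PW4"): 5,
                  ("PW3", "PW4"): 0, ("PW1", "PW4"): 0, ("PW2", "PW3"): 0}
        for (a, b), c in expect.items():
            assert len(members[a] & members[b]) == c
        for sid, size in zip(coll.set_ids, spec.set_sizes):
            assert len(members[sid]) == size

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            gen_pathway_collection(SyntheticSpec(set_sizes=(5, 10),
                                                 planted_overlaps={(0, 1): 6}))

    def test_deterministic(self):
        spec = SyntheticSpec(rng_seed=1)
        c1, c2 = gen_pathway_collection(spec), gen_pathway_collection(spec)
        assert all(a.members == b.members for a, b in zip(c1, c2))


class TestCandidateGenes:
    def test_whole_universe_hits_everything(self):
        spec = SyntheticSpec(universe_size=200, set_sizes=(20, 20),
                             planted_overlaps={})
        coll = gen_pathway_collection(spec)
        cand = gen_candidate_genes(coll, ("PW1",), 10.0, 200,
                                   np.random.default_rng(0))
        assert set(cand) == set(coll.universe)

    def test_sample_is_unique_and_deterministic(self):
        spec = SyntheticSpec()
        coll = gen_pathway_collection(spec)
        c1 = gen_candidate_genes(coll, ("PW1",), 10.0, 100, np.random.default_rng(9))
        c2 = gen_candidate_genes(coll, ("PW1",), 10.0, 100, np.random.default_rng(9))
        assert c1 == c2 and len(set(c1)) == 100

    def test_oversized_request_rejected(self):
        spec = SyntheticSpec(universe_size=50, set_sizes=(10,), planted_overlaps={})
        coll = gen_pathway_collection(spec)
        with pytest.raises(ValueError):
            gen_candidate_genes(coll, (), 1.0, 51, np.random.default_rng(0))

    def test_enrichment_factor_below_one_rejected(self):
        spec = SyntheticSpec(universe_size=50, set_sizes=(10,), planted_overlaps={})
        coll = gen_pathway_collection(spec)
        with pytest.raises(ValueError):
            gen_candidate_genes(coll, ("PW1",), 0.5, 10, np.random.default_rng(0))


class TestPlantedHost:
    def test_unique_cut_linker_recovered(self):
        spec = SyntheticSpec(host_n=20, host_m=15, n_seeds=4, n_true_linkers=1,
                             rng_seed=0)
        net, seeds, linkers = gen_host_with_planted_module(spec)
        r = steiner_tree_greedy(net, seeds)
        assert set(linkers) <= set(r.node_set)

    def test_linkers_are_cut_vertices_between_clusters(self):
        spec = SyntheticSpec(host_n=60, host_m=100, n_seeds=8, n_true_linkers=3,
                             rng_seed=4)
        net, seeds, linkers = gen_host_with_planted_module(spec)
        for linker in linkers:
            g = net.copy()
            g.remove_node(linker)
            comps = list(nx.connected_components(g))
            in_one = any(set(seeds) <= c for c in comps)
            assert not in_one, f"removing {linker} should split the seed set"

    def test_no_linkers_single_clique(self):
        spec = SyntheticSpec(host_n=20, host_m=15, n_seeds=4, n_true_linkers=0,
                             rng_seed=2)
        net, seeds, linkers = gen_host_with_planted_module(spec)
        assert linkers == []
        r = steiner_tree_greedy(net, seeds)
        assert r.linkers == frozenset()

    def test_preferential_attachment_host(self):
        spec = SyntheticSpec(host_n=80, host_m=150, n_seeds=6, n_true_linkers=2,
                             host_model="preferential-attachment", rng_seed=3)
        net, seeds, linkers = gen_host_with_planted_module(spec)
        assert net.number_of_nodes() == 80

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValueError):
            gen_host_with_planted_module(SyntheticSpec(host_n=5, n_seeds=8,
                                                       n_true_linkers=3))


def test_written_inputs_regenerate_bit_identically(tmp_path):
    spec = SyntheticSpec(rng_seed=21)
    p1 = write_synthetic_inputs(spec, tmp_path / "a")
    p2 = write_synthetic_inputs(spec, tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()
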