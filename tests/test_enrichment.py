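"""Hypergeometric test, BH adjustment and the enrichment/filter cascade."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathcrosstalk.enrichment import (bh_adjust, enrich, filter_results,
                                      hypergeometric_pvalue)
from pathcrosstalk.io import GeneSet, GeneSetCollection
from pathcrosstalk.synthetic import SyntheticSpec, gen_candidate_genes, gen_pathway_collection


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Exhaustive combinatorial sum P(X >= k), independent of scipy."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_pvalue(0, 10, 5, 100) == 1.0

    def test_degenerate_full_draw(self):
        assert hypergeometric_pvalue(7, 7, 7, 7) == 1.0

    def test_worked_example(self):
        # N=10, K=4, n=5: P(X>=3) = (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5)
        assert hypergeometric_pvalue(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-15)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(1, 11, 5, 10)

    @pytest.mark.parametrize("N", [5, 12, 19, 25])
    def test_matches_enumeration_oracle(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeometric_pvalue(k, K, n, N) == pytest.approx(
                        hypergeom_tail_oracle(k, K, n, N), abs=1e-12)


class TestBH:
    def test_single_value_identity(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_hand_computed_step_up(self):
        # 0.01*3, 0.02*3/2, 0.03*3/3 then running min from the top
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bounds_and_input_order(self, p):
        adj = bh_adjust(p)
        assert all(a >= raw - 1e-12 and a <= 1.0 for a, raw in zip(adj, p))

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 50)))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


@pytest.fixture
def small_collection():
    return GeneSetCollection([
        GeneSet("SetA", "", frozenset({"G1", "G2", "G3", "G4"})),
        GeneSet("SetB", "", frozenset({"G3", "G4", "G5", "G6"})),
        GeneSet("SetC", "", frozenset({"G7", "G8"})),
    ])


class TestEnrich:
    def test_full_overlap_single_set(self):
        coll = GeneSetCollection([GeneSet("S", "", frozenset({"A", "B", "C"}))],
                                 universe=frozenset({"A", "B", "C", "D", "E"}))
        res = enrich(["A", "B", "C"], coll)
        assert len(res) == 1 and res[0].k == res[0].K == 3
        assert res[0].p_raw == pytest.approx(hypergeom_tail_oracle(3, 3, 3, 5))

    def test_zero_overlap_sets_not_reported(self, small_collection):
        res = enrich(["G1", "G2"], small_collection)
        assert "SetC" not in {r.set_id for r in res}

    def test_order_invariance(self, small_collection):
        a = enrich(["G1", "G2", "G3"], small_collection)
        b = enrich(["G3", "G1", "G2"], small_collection)
        assert [(r.set_id, r.p_raw, r.p_bh) for r in a] == \
               [(r.set_id, r.p_raw, r.p_bh) for r in b]

    def test_candidates_outside_universe_excluded(self, small_collection):
        res = enrich(["G1", "G2", "NOT_A_GENE"], small_collection)
        assert all(r.n == 2 for r in res)

    def test_all_candidates_outside_universe_errors(self, small_collection):
        with pytest.raises(ValueError):
            enrich(["X1", "X2"], small_collection)

    def test_planted_true_set_ranks_first(self):
        # one true set of 50 genes in a 2000-gene universe, 10-fold weight
        spec = SyntheticSpec(rng_seed=5)
        coll = gen_pathway_collection(spec)
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(200):
            cand = gen_candidate_genes(coll, ("PW1",), 10.0,
                                       spec.n_candidates, rng)
            res = enrich(cand, coll)
            wins += res[0].set_id == "PW1"
        assert wins >= 190

    def test_null_pvalues_are_roughly_uniform(self):
        # factor 1 removes the planted signal; discrete upper-tail p-values
        # are conservative, so the check is one-sided
        spec = SyntheticSpec(rng_seed=11)
        coll = gen_pathway_collection(spec)
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            cand = gen_candidate_genes(coll, (), 1.0, spec.n_candidates, rng)
            res = enrich(cand, coll)
            by_id = {r.set_id: r.p_raw for r in res}
            if "PW1" in by_id:
                pvals.append(by_id["PW1"])
        assert np.mean(pvals) > 0.35
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.10


class TestFilterResults:
    def _mk(self, set_id, k, p_bh):
        return type("R", (), {"set_id": set_id, "k": k, "p_bh": p_bh})()

    def test_min_genes_cut(self):
        res = [self._mk("A", 4, 1e-6), self._mk("B", 5, 1e-6)]
        assert [r.set_id for r in filter_results(res)] == ["B"]

    def test_p_bh_strict_cut(self):
        res = [self._mk("A", 10, 0.02), self._mk("B", 10, 0.01), self._mk("C", 10, 0.0099)]
        assert [r.set_id for r in filter_results(res)] == ["C"]

    def test_depth_filter_and_missing_depth(self):
        res = [self._mk("A", 6, 1e-6), self._mk("B", 6, 1e-6)]
        kept = filter_results(res, min_depth=4, depth_map={"A": 5, "B": 3})
        assert [r.set_id for r in kept] == ["A"]
        with pytest.raises(ValueError, match="depth"):
            filter_results(res, min_depth=4, depth_map={"A": 5})
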