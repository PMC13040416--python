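"""Hypergeometric over-representation analysis and multiple-testing adjustment."""

import math
from fractions import Fraction

import numpy as np
import pytest

from eposcreen import (
    AnnotationSet, SimConfig, bh_adjust, build_universe, enrich, gen_annotations,
    hypergeom_upper_tail, storey_q,
)


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Brute-force enumeration oracle: sum of hypergeometric point masses."""
    total = math.comb(N, n)
    return sum(
        (Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
         for j in range(k, min(n, K) + 1)),
        Fraction(0),
    )


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 4, 5, 10) == 1.0

    def test_small_case_against_enumeration(self):
        # N=10, K=4, n=5, k=4: 6 favourable draws of C(10,5)=252
        expected = exact_upper_tail(4, 4, 5, 10)
        assert expected == Fraction(6, 252)
        assert hypergeom_upper_tail(4, 4, 5, 10) == pytest.approx(
            float(expected), rel=1e-12)

    def test_degenerate_universe(self):
        assert hypergeom_upper_tail(5, 5, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,K,n,N", [(-1, 4, 5, 10), (5, 4, 5, 10),
                                         (2, 11, 5, 10), (2, 4, 11, 10)])
    def test_bound_violations_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(k, K, n, N)

    def test_random_sample_against_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            N = int(rng.integers(2, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                float(exact_upper_tail(k, K, n, N)), rel=1e-10, abs=1e-300)


def bh_stepup_oracle(p):
    """Hand-rolled BH step-up with monotonicity enforcement."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBHAdjust:
    def test_hand_worked_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_against_stepup_oracle_and_dominance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            assert list(adj) == pytest.approx(bh_stepup_oracle(list(p)))
            assert (adj >= p - 1e-15).all()

    def test_order_invariance_and_monotonicity(self):
        p = [0.04, 0.001, 0.2, 0.04, 0.9]
        adj = bh_adjust(p)
        perm = [2, 0, 4, 1, 3]
        adj_perm = bh_adjust([p[i] for i in perm])
        assert [adj[i] for i in perm] == pytest.approx(list(adj_perm))
        sorted_adj = bh_adjust(sorted(p))
        assert list(sorted_adj) == sorted(sorted_adj)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


@pytest.fixture
def small_annotation():
    universe = [f"g{i}" for i in range(40)]
    terms = {
        "T_ALL": ("whole universe", frozenset(universe)),
        "T_A": ("first ten", frozenset(universe[:10])),
        "T_B": ("last twenty", frozenset(universe[20:])),
    }
    return AnnotationSet(terms=terms), universe


class TestEnrich:
    def test_input_equal_universe_fold_enrichment_one(self, small_annotation):
        annotation, universe = small_annotation
        results, dropped = enrich(universe, annotation,
                                  build_universe("measured", universe))
        assert dropped == []
        for r in results:
            assert r.fold_enrichment == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_rational_identity_fold_enrichment(self, small_annotation):
        annotation, universe = small_annotation
        results, _ = enrich(universe[:12], annotation,
                            build_universe("measured", universe))
        for r in results:
            # (k/n)/(K/N) * (K/N) * n == k exactly in rational arithmetic
            assert Fraction(r.k, r.n) / Fraction(r.K, r.N) * Fraction(r.K, r.N) \
                * r.n == r.k

    def test_results_sorted_with_total_tiebreak(self, small_annotation):
        annotation, universe = small_annotation
        results, _ = enrich(universe[:12], annotation,
                            build_universe("measured", universe))
        keys = [(r.p, r.term_id) for r in results]
        assert keys == sorted(keys)

    def test_outside_universe_genes_dropped_with_warning(self, small_annotation):
        annotation, universe = small_annotation
        with pytest.warns(UserWarning, match="dropped"):
            results, dropped = enrich(universe[:5] + ["ALIEN"], annotation,
                                      build_universe("measured", universe))
        assert dropped == ["ALIEN"]
        assert results[0].n == 5

    def test_biotype_exclusion(self, small_annotation):
        annotation, universe = small_annotation
        with pytest.warns(UserWarning):
            results, dropped = enrich(
                universe[:6], annotation, build_universe("measured", universe),
                exclude_biotypes={"pseudogene"},
                biotypes={"g0": "pseudogene", "g1": "protein_coding"})
        assert dropped == ["g0"]
        assert results[0].n == 5

    def test_empty_mapped_input_rejected(self, small_annotation):
        annotation, universe = small_annotation
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            enrich(["ALIEN"], annotation, build_universe("measured", universe))

    def test_planted_term_recovered_first(self):
        cfg = SimConfig(seed=6, n_terms=30, term_size_range=(10, 30),
                        planted_terms=1, planted_term_size=20,
                        planted_term_input_fraction=0.8)
        universe = [f"g{i}" for i in range(400)]
        input_genes = universe[:25]
        annotation, truth = gen_annotations(cfg, universe, input_genes)
        results, _ = enrich(input_genes, annotation,
                            build_universe("measured", universe))
        assert results[0].term_id in truth.enriched_terms
        assert results[0].p_adj <= 0.05

    def test_storey_q_between_zero_and_bh(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        q = storey_q(p)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q <= bh_adjust(p) + 1e-12).all()


class TestUniverse:
    def test_modes_and_sizes(self):
        uni = build_universe("measured", ["a", "b", "c"])
        assert uni.N == 3
        with pytest.raises(ValueError):
            build_universe("partial", ["a"])
        with pytest.raises(ValueError):
            build_universe("genome", [])

    def test_measured_universe_raises_fold_enrichment(self):
        """Genome-wide backgrounds inflate apparent enrichment: for terms
        concentrated in the measured gene space, fold enrichment under the
        genome universe is at least that under the measured universe."""
        rng = np.random.default_rng(14)
        genome = [f"g{i}" for i in range(500)]
        measured = genome[:100]
        input_genes = measured[:20]
        terms = {f"T{i}": (f"t{i}", frozenset(
            rng.choice(measured, 30, replace=False)) | frozenset(
            rng.choice(genome[100:], 10, replace=False)))
            for i in range(10)}
        annotation = AnnotationSet(terms=terms)
        res_measured, _ = enrich(input_genes, annotation,
                                 build_universe("measured", measured))
        res_genome, _ = enrich(input_genes, annotation,
                               build_universe("genome", genome))
        fm = {r.term_id: r.fold_enrichment for r in res_measured}
        fg = {r.term_id: r.fold_enrichment for r in res_genome}
        for tid in fm:
            assert fm[tid] <= fg[tid] + 1e-12
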