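"""Hypergeometric ORA and the bootstrap re-ranking statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathweave import (
    DomainError,
    EnrichmentConfig,
    InputError,
    bootstrap_null,
    bootstrap_p,
    build_store,
    enrich,
    hypergeometric_upper_tail,
    score_pathways,
)
from pathweave.enrichment import is_at_least_as_extreme

from conftest import brute_force_upper_tail, enumerate_null_probabilities, gene_list


class TestHypergeometricUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeometric_upper_tail(0, 5, 3, 10) == 1.0

    def test_known_value_4_4_5_10(self):
        # all 4 pathway members drawn in 5 of 10: C(6,1)/C(10,5) = 6/252
        assert hypergeometric_upper_tail(4, 4, 5, 10) == pytest.approx(
            6 / 252, rel=1e-12
        )

    def test_known_value_2_3_3_6(self):
        expected = brute_force_upper_tail(2, 3, 3, 6)
        assert hypergeometric_upper_tail(2, 3, 3, 6) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("N", [6, 9])
    def test_matches_enumeration_small(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    expected = brute_force_upper_tail(k, K, n, N)
                    got = hypergeometric_upper_tail(k, K, n, N)
                    assert got == pytest.approx(expected, rel=1e-10, abs=1e-14)

    @pytest.mark.parametrize(
        "k,K,n,N", [(5, 4, 5, 10), (1, 11, 3, 10), (1, 3, 11, 10), (2, 1, 5, 10)]
    )
    def test_bound_violations_raise(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeometric_upper_tail(k, K, n, N)

    def test_far_tail_precision(self):
        # P[X >= K] = C(N-K, n-K)/C(N,n), exact in integer arithmetic
        k = K = 20
        n, N = 100, 2000
        expected = math.comb(N - K, n - K) / math.comb(N, n)
        assert hypergeometric_upper_tail(k, K, n, N) == pytest.approx(
            expected, rel=1e-11
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_nonincreasing_in_k(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [
            hypergeometric_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestScorePathways:
    def test_counts_and_p(self):
        store = build_store("syn", {"p1": {f"g{i}" for i in range(1, 5)},
                                    "px": {f"g{i}" for i in range(1, 11)}})
        rows = score_pathways(gene_list(["G1", "G2", "G3"]), store)
        by_id = {r[0]: r for r in rows}
        _, k, K, p = by_id["p1"]
        assert (k, K) == (3, 4)
        assert p == pytest.approx(brute_force_upper_tail(3, 4, 3, 10), rel=1e-10)

    def test_zero_overlap_pathway_absent(self, toy_store):
        rows = score_pathways(gene_list(["G1", "G2"]), toy_store)
        assert {r[0] for r in rows} == {"p1"}

    def test_full_background_input_gives_p_one(self, toy_store):
        rows = score_pathways(
            gene_list(sorted(toy_store.background_genes)), toy_store
        )
        assert all(r[3] == pytest.approx(1.0) for r in rows)

    def test_empty_list_raises(self, toy_store):
        with pytest.raises(InputError):
            score_pathways(gene_list([]), toy_store)

    def test_unrestricted_input_raises(self, toy_store):
        with pytest.raises(DomainError):
            score_pathways(gene_list(["G1", "ZZZ"]), toy_store)


class TestBootstrapNull:
    def test_full_draw_gives_full_cells(self, toy_store):
        N = toy_store.n_background
        null = bootstrap_null(
            toy_store, n=N, config=EnrichmentConfig(n_resamples=1, seed=0)
        )
        sizes = [len(toy_store.pathway_to_genes[p]) for p in toy_store.pathways]
        assert null.counts == {(K, K): sizes.count(K) for K in set(sizes)}

    def test_single_covering_pathway(self):
        store = build_store("syn", {"p1": {"a", "b", "c", "d"}})
        null = bootstrap_null(
            store, n=2, config=EnrichmentConfig(n_resamples=7, seed=1)
        )
        assert null.counts == {(2, 4): 7}
        assert null.frequencies()[(2, 4)] == 1.0

    def test_frequencies_sum_to_one(self, random_store):
        store = random_store(3)
        null = bootstrap_null(
            store, n=5, config=EnrichmentConfig(n_resamples=200, seed=2)
        )
        assert sum(null.frequencies().values()) == pytest.approx(1.0)
        assert null.total == 200 * len(store.pathways)

    def test_converges_to_enumerated_probabilities(self):
        """4-gene background, 2 pathways, n=2: the 6 possible subsets are
        enumerable, and resampled frequencies must converge to them."""
        store = build_store("syn", {"p1": {"a", "b", "c"}, "p2": {"c", "d"}})
        exact = enumerate_null_probabilities(store, n=2)
        R = 20000
        null = bootstrap_null(
            store, n=2, config=EnrichmentConfig(n_resamples=R, seed=3)
        )
        freqs = null.frequencies()
        assert set(freqs) <= set(exact)
        for cell, p_exact in exact.items():
            se = math.sqrt(p_exact * (1 - p_exact) / (2 * R))
            assert abs(freqs.get(cell, 0.0) - p_exact) <= max(4 * se, 1e-9)

    def test_n_larger_than_background_raises(self, toy_store):
        with pytest.raises(DomainError):
            bootstrap_null(toy_store, n=99, config=EnrichmentConfig())

    def test_deterministic_given_seed(self, random_store):
        store = random_store(4)
        cfg = EnrichmentConfig(n_resamples=50, seed=11)
        assert bootstrap_null(store, 4, cfg) == bootstrap_null(store, 4, cfg)


class TestBootstrapP:
    def test_unobserved_cell_floor(self, toy_store):
        null = bootstrap_null(
            toy_store, n=3, config=EnrichmentConfig(n_resamples=10, seed=0)
        )
        T = null.total
        # maximally dense huge cell can never occur in this store
        assert bootstrap_p((50, 50), null) == pytest.approx(1 / (T + 1))

    def test_cell_matching_every_observation(self):
        store = build_store("syn", {"p1": {"a", "b", "c", "d"}})
        null = bootstrap_null(
            store, n=2, config=EnrichmentConfig(n_resamples=9, seed=0)
        )
        assert bootstrap_p((1, 4), null) == pytest.approx(1.0)

    def test_matches_hand_enumeration_on_toy_store(self):
        """Two-pathway store with an exhaustively enumerable null."""
        store = build_store("syn", {"p1": {"a", "b", "c"}, "p2": {"c", "d"}})
        R = 5000
        null = bootstrap_null(
            store, n=2, config=EnrichmentConfig(n_resamples=R, seed=5)
        )
        # independent recount of the extremeness sum from the raw counts
        for observed in [(1, 2), (2, 3), (1, 3)]:
            m = sum(
                c
                for (k2, K2), c in null.counts.items()
                if k2 >= observed[0] and k2 / K2 >= observed[0] / observed[1]
            )
            assert bootstrap_p(observed, null) == pytest.approx(
                (m + 1) / (null.total + 1)
            )

    def test_empty_null_raises(self):
        from pathweave import EnrichmentNullTable

        with pytest.raises(InputError):
            bootstrap_p((1, 2), EnrichmentNullTable({}, 0, 0, 1))


def test_extremeness_ordering():
    # denser and at least as many genes
    assert is_at_least_as_extreme((4, 8), (2, 8))
    assert is_at_least_as_extreme((2, 4), (2, 8))
    assert not is_at_least_as_extreme((1, 2), (2, 4))  # k' < k
    assert not is_at_least_as_extreme((2, 10), (2, 8))  # less dense
    assert is_at_least_as_extreme((3, 6), (3, 6))


class TestEnrich:
    def test_perfectly_enriched_pathway_ranks_first(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(60)]
        memberships = {"target": set(genes[:8])}
        for j in range(6):
            members = rng.choice(60, size=15, replace=False)
            memberships[f"bg{j}"] = {genes[i] for i in members}
        store = build_store("syn", memberships)
        results = enrich(
            gene_list([g.upper() for g in genes[:8]]),
            store,
            EnrichmentConfig(hyper_p_threshold=1.0, bootstrap_cutoff_percent=100,
                             n_resamples=2000, seed=0),
        )
        assert results[0].pathway_id == "target"
        assert results[0].rank == 1
        assert results[0].k == results[0].K == 8

    def test_disabled_filters_keep_all_and_order_by_boot_p(self, random_store):
        store = random_store(9)
        gl = gene_list(sorted(store.background_genes)[:8])
        cfg = EnrichmentConfig(hyper_p_threshold=1.0, bootstrap_cutoff_percent=100,
                               n_resamples=300, seed=1)
        results = enrich(gl, store, cfg)
        scored_ids = {r[0] for r in score_pathways(gl, store)}
        assert {r.pathway_id for r in results} == scored_ids
        boot = [r.boot_p for r in results]
        assert boot == sorted(boot)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_result_invariant_bounds(self, random_store):
        store = random_store(12)
        gl = gene_list(sorted(store.background_genes)[:10])
        for r in enrich(store=store, genes=gl,
                        config=EnrichmentConfig(hyper_p_threshold=1.0,
                                                bootstrap_cutoff_percent=100,
                                                n_resamples=100, seed=0)):
            assert 1 <= r.k <= min(r.K, r.n)
            assert r.K <= r.N and r.n <= r.N
            assert 0 < r.boot_p <= 1 and 0 < r.hyper_p <= 1

    def test_bit_identical_given_seed(self, random_store):
        store = random_store(5)
        gl = gene_list(sorted(store.background_genes)[:6])
        cfg = EnrichmentConfig(n_resamples=200, seed=42,
                               hyper_p_threshold=1.0, bootstrap_cutoff_percent=100)
        assert enrich(gl, store, cfg) == enrich(gl, store, cfg)

    def test_null_calibration_boot_p_conservative(self):
        """Bootstrap p-values of uniformly random gene lists are
        stochastically >= uniform: the one-sided KS statistic D+ stays
        within a generous tolerance (the statistic is discrete, so its
        largest atom sits below 1 and the ECDF jumps early there), and the
        low tail where significance is decided is strictly conservative."""
        rng = np.random.default_rng(2024)
        genes = [f"g{i:03d}" for i in range(40)]
        memberships = {
            f"p{j}": {genes[i] for i in rng.choice(40, size=10, replace=False)}
            for j in range(5)
        }
        store = build_store("syn", memberships)
        null = bootstrap_null(
            store, n=6, config=EnrichmentConfig(n_resamples=3000, seed=0)
        )
        boot_ps = []
        bg = sorted(store.background_genes)
        for _ in range(500):
            draw = rng.choice(len(bg), size=6, replace=False)
            s = {bg[i] for i in draw}
            for p in store.pathways:
                k = len(s & store.pathway_to_genes[p])
                if k:
                    boot_ps.append(bootstrap_p((k, len(store.pathway_to_genes[p])),
                                               null))
        b = np.sort(np.asarray(boot_ps))
        d_plus = float(np.max(np.arange(1, len(b) + 1) / len(b) - b))
        assert d_plus <= 0.10
        for alpha in (0.01, 0.05, 0.10):
            se = math.sqrt(alpha * (1 - alpha) / len(b))
            assert np.mean(b <= alpha) <= alpha + 3 * se
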