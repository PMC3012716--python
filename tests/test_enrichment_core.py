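"""Upper-level statistics against independent oracles and printed tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nease.annotation_io import GeneList
from nease.enrichment_core import (
    ContingencyCounts,
    bh_adjust,
    build_contingency,
    ease_score,
    fisher_upper_tail,
    gene_enrich,
    run_ease,
    significant,
)
from nease.synthetic import PlantedTerm, SyntheticSpec, make_gene_list, make_universe


def exact_upper_tail(k, n, K, N):
    """Independent oracle: exact integer-arithmetic hypergeometric tail."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / math.comb(N, n)


@st.composite
def valid_counts(draw):
    N = draw(st.integers(min_value=2, max_value=500))
    n = draw(st.integers(min_value=1, max_value=N))
    K = draw(st.integers(min_value=1, max_value=N))
    k = draw(st.integers(min_value=max(0, n + K - N), max_value=min(n, K)))
    return ContingencyCounts(k, n, K, N)


class TestContingency:
    def test_fully_contained_list(self, toy_universe):
        counts = build_contingency(GeneList.from_iterable(["g1", "g2", "g3"]), "A", toy_universe)
        assert counts == ContingencyCounts(3, 3, 5, 10)

    def test_unannotated_identifiers_excluded(self, toy_universe):
        genes = GeneList.from_iterable(["g1", "g2", "g3", "zz1", "zz2"])
        assert build_contingency(genes, "A", toy_universe) == ContingencyCounts(3, 3, 5, 10)

    def test_unknown_term_and_disjoint_list_error(self, toy_universe):
        with pytest.raises(KeyError):
            build_contingency(GeneList.from_iterable(["g1"]), "nope", toy_universe)
        with pytest.raises(ValueError):
            build_contingency(GeneList.from_iterable(["zz"]), "A", toy_universe)

    def test_matches_naive_set_oracle_on_random_universes(self):
        rng = np.random.default_rng(42)
        for draw in range(100):
            spec = SyntheticSpec(
                n_genes=200, n_terms=12, term_size_range=(10, 40),
                list_size=int(rng.integers(10, 80)), seed=draw,
            )
            universe = make_universe(spec)
            genes, _ = make_gene_list(universe, spec)
            term = sorted(universe.term_to_genes)[int(rng.integers(0, 12))]
            counts = build_contingency(genes, term, universe)
            gene_set, term_set = set(genes), set(universe.term_to_genes[term])
            background = set().union(*universe.term_to_genes.values())
            assert counts.list_hits == len(gene_set & term_set)
            assert counts.list_size == len(gene_set & background)
            assert counts.pop_hits == len(term_set)
            assert counts.pop_size == len(background)

    @pytest.mark.parametrize(
        "quad",
        [(5, 3, 5, 10), (3, 3, 11, 10), (0, 3, 8, 10), (2, 0, 5, 10)],
    )
    def test_invalid_quadruples_rejected(self, quad):
        with pytest.raises(ValueError):
            ContingencyCounts(*quad)


class TestFisherTail:
    def test_closed_form_three_of_three(self):
        # all 3 of a 3-gene term inside a 122-gene list from 735
        p = fisher_upper_tail(ContingencyCounts(3, 122, 3, 735))
        closed = (122 * 121 * 120) / (735 * 734 * 733)
        assert p == pytest.approx(closed, rel=1e-12)

    def test_closed_form_two_of_two(self):
        p = fisher_upper_tail(ContingencyCounts(2, 150, 2, 818))
        assert p == pytest.approx((150 * 149) / (818 * 817), rel=1e-12)

    def test_zero_hits_gives_one(self):
        assert fisher_upper_tail(ContingencyCounts(0, 10, 5, 100)) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(counts=valid_counts())
    def test_equals_exact_summation_oracle(self, counts):
        expected = exact_upper_tail(
            counts.list_hits, counts.list_size, counts.pop_hits, counts.pop_size
        )
        assert fisher_upper_tail(counts) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_list_hits(self):
        n, K, N = 40, 30, 200
        values = [
            fisher_upper_tail(ContingencyCounts(k, n, K, N))
            for k in range(max(0, n + K - N), min(n, K) + 1)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    @settings(derandomize=True, max_examples=100)
    @given(counts=valid_counts())
    def test_complement_identity(self, counts):
        """P(X >= k) + P(X <= k-1) = 1, lower tail from the factorial oracle."""
        k, n, K, N = counts.list_hits, counts.list_size, counts.pop_hits, counts.pop_size
        lower = sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(max(0, n + K - N), k)
        ) / math.comb(N, n)
        assert fisher_upper_tail(counts) + lower == pytest.approx(1.0, abs=1e-12)


class TestEaseScore:
    def test_jackknife_is_two_term_pmf_sum(self):
        counts = ContingencyCounts(3, 122, 3, 735)
        assert ease_score(counts) == pytest.approx(exact_upper_tail(2, 122, 3, 735), rel=1e-12)
        assert ease_score(counts) > fisher_upper_tail(counts)

    @pytest.mark.parametrize("counts", [ContingencyCounts(0, 10, 5, 100),
                                        ContingencyCounts(1, 10, 5, 100),
                                        ContingencyCounts(1, 3, 7, 20)])
    def test_clamps_to_one_for_at_most_one_hit(self, counts):
        assert ease_score(counts) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(counts=valid_counts())
    def test_never_below_plain_fisher(self, counts):
        assert fisher_upper_tail(counts) <= ease_score(counts)


class TestGeneEnrich:
    @pytest.mark.parametrize(
        "quad,expected",
        [((27, 277, 104, 1534), 8.22), ((24, 1451, 96, 10985), 11.32)],
    )
    def test_printed_values(self, quad, expected):
        assert round(gene_enrich(ContingencyCounts(*quad)), 2) == expected

    def test_zero_at_exact_expectation(self):
        # expected hits = 10 * 50 / 100 = 5
        assert gene_enrich(ContingencyCounts(5, 10, 50, 100)) == pytest.approx(0.0)


def bh_oracle(pvalues):
    """Independent step-up oracle: adj_i = min_{j>=i} p_(j) * m / j, clipped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_ties_stay_at_common_value(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_empty_input_gives_empty_output(self):
        assert bh_adjust([]).size == 0

    @settings(derandomize=True, max_examples=100)
    @given(
        pvalues=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1, max_size=40,
        )
    )
    def test_matches_step_up_oracle_and_bounds(self, pvalues):
        adjusted = bh_adjust(pvalues)
        assert adjusted == pytest.approx(bh_oracle(pvalues), rel=1e-12)
        assert np.all(adjusted >= np.asarray(pvalues) - 1e-15)
        assert np.all(adjusted <= 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        pvalues=st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=20),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_permutation_equivariance(self, pvalues, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(pvalues))
        direct = bh_adjust(pvalues)
        permuted = bh_adjust([pvalues[i] for i in perm])
        assert permuted == pytest.approx([direct[i] for i in perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestRunEase:
    def test_single_term_exact_p(self, toy_universe):
        universe = type(toy_universe)("one", {"A": {"g1", "g2", "g3", "g4", "g5"},
                                              "Z": {"g6", "g7", "g8", "g9", "g10"}})
        genes = GeneList.from_iterable(["g1", "g2", "g3"])
        results = run_ease(genes, [universe], min_hits=3, alpha=1.0)
        (result,) = results
        # C(5,3)C(5,0)/C(10,3) = 10/120
        assert result.term == "A"
        assert result.fisher_p == pytest.approx(10 / 120, rel=1e-12)
        assert result.corrected_p == pytest.approx(result.fisher_p)

    def test_alpha_one_min_hits_one_tests_every_intersecting_term(self, toy_universe):
        genes = GeneList.from_iterable(["g1", "g4", "g9"])
        results = run_ease(genes, [toy_universe], min_hits=1, alpha=1.0)
        intersecting = {
            t for t, members in toy_universe.term_to_genes.items()
            if members & set(genes)
        }
        assert {r.term for r in results} == intersecting

    def test_no_term_reaching_min_hits_returns_empty(self, toy_universe, caplog):
        genes = GeneList.from_iterable(["g1", "g6", "g9"])
        assert run_ease(genes, [toy_universe], min_hits=3) == []

    def test_planted_term_ranks_first(self):
        """A strong planted term tops the raw-p ranking in >=95/100 replicates."""
        wins = 0
        for seed in range(100):
            spec = SyntheticSpec(
                n_genes=1000, n_terms=51, term_size_range=(20, 50),
                planted_terms=(PlantedTerm("planted", 10.0),),
                list_size=100, seed=seed,
            )
            universe = make_universe(spec)
            genes, _ = make_gene_list(universe, spec)
            results = run_ease(genes, [universe], min_hits=1, alpha=1.0)
            best = min(results, key=lambda r: r.fisher_p)
            wins += best.term == "planted"
        assert wins >= 95

    def test_results_sorted_and_flagged(self, toy_universe):
        genes = GeneList.from_iterable(["g1", "g2", "g4", "g9"])
        results = run_ease(genes, [toy_universe], min_hits=1, alpha=1.0)
        corrected = [r.corrected_p for r in results]
        assert corrected == sorted(corrected)
        assert all(r.over_represented for r in results)
        assert significant(results) == results
        for r in results:
            assert 0 < r.fisher_p <= r.ease_p
            assert r.fisher_p <= r.corrected_p <= 1.0
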