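"""Spanning-read selection, concordant-read fraction, and the shuffle null."""

import itertools

import numpy as np
import pytest

from epientropy.concordance import (
    cgi_pair_table,
    concordance_fraction,
    exact_null_mean,
    per_read_cgi_mean,
    select_spanning_reads,
    shuffle_null,
)
from epientropy.io import Feature
from tests.conftest import make_read

CGI_A = Feature("cgiA", "chr1", 1000, 1100, "cgi")
CGI_B = Feature("cgiB", "chr1", 5000, 5100, "cgi")


def spanning_read(rid, mean_a, mean_b, n_calls=4):
    """A read spanning both islands with the requested per-island means."""
    calls = []
    for base, mean in ((1000, mean_a), (5000, mean_b)):
        k = int(round(mean * n_calls))
        calls += [(base + 10 * i, 1 if i < k else 0) for i in range(n_calls)]
    return make_read(rid, calls, start=900, end=5200)


class TestSelectSpanningReads:
    def test_read_stopping_one_base_short_does_not_span(self):
        reads = [make_read(f"r{i}", [(1000 + j, 1) for j in range(0, 99, 10)],
                           start=900, end=1099)  # ends 1 bp inside the CGI
                 for i in range(12)]
        assert select_spanning_reads(reads, [CGI_A, CGI_B]) == {}

    def test_reads_containing_two_whole_cgis_are_retained(self):
        reads = [spanning_read(f"r{i}", 0.5, 0.5) for i in range(12)]
        spanning = select_spanning_reads(reads, [CGI_A, CGI_B])
        assert set(spanning) == {"cgiA", "cgiB"}
        assert all(len(v) == 12 for v in spanning.values())

    def test_cgi_with_nine_reads_is_discarded(self):
        reads = [spanning_read(f"r{i}", 0.5, 0.5) for i in range(9)]
        assert select_spanning_reads(reads, [CGI_A, CGI_B]) == {}

    def test_reads_spanning_single_cgi_dropped_first(self):
        # 12 reads span only island A -> dropped before the per-CGI count
        only_a = [make_read(f"a{i}", [(1000 + 10 * j, 1) for j in range(11)],
                            start=900, end=1200) for i in range(12)]
        assert select_spanning_reads(only_a, [CGI_A, CGI_B]) == {}


class TestPerReadCgiMean:
    def test_mean_of_inside_calls(self):
        read = make_read("r", [(1010, 1), (1020, 1), (1030, 0), (1040, 0),
                               (2000, 1)], start=900, end=2100)
        assert per_read_cgi_mean(read, CGI_A) == pytest.approx(0.5)

    def test_no_calls_inside_is_missing(self):
        read = make_read("r", [(2000, 1)], start=900, end=2100)
        assert np.isnan(per_read_cgi_mean(read, CGI_A))

    def test_all_methylated(self):
        read = make_read("r", [(1010, 1), (1020, 1)], start=900, end=1200)
        assert per_read_cgi_mean(read, CGI_A) == 1.0


class TestConcordanceFraction:
    def test_identical_pairing_is_fully_concordant(self):
        x = np.array([0.1, 0.2, 0.8, 0.9])
        values = np.column_stack([x, x])
        assert concordance_fraction(values, np.median(x), np.median(x)) == 1.0

    def test_reversed_ranks_fully_discordant(self):
        x = np.array([0.1, 0.2, 0.8, 0.9])
        values = np.column_stack([x, x[::-1]])
        assert concordance_fraction(values, np.median(x), np.median(x)) == 0.0

    def test_exhaustive_mean_over_pairings_is_half(self):
        """All 24 pairings of 4 distinct values average to concordance 0.5."""
        x = np.array([0.1, 0.2, 0.8, 0.9])
        mx = my = float(np.median(x))
        fracs = [
            concordance_fraction(np.column_stack([x, np.array(perm)]), mx, my)
            for perm in itertools.permutations(x)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=1e-12)

    def test_ties_count_to_the_low_side(self):
        values = [(0.5, 0.5), (0.5, 0.5)]
        # both at the median: x <= mx and y <= my -> concordant
        assert concordance_fraction(values, 0.5, 0.5) == 1.0

    def test_invariant_under_joint_read_permutation(self):
        rng = np.random.default_rng(4)
        values = rng.random((15, 2))
        mx, my = np.median(values[:, 0]), np.median(values[:, 1])
        base = concordance_fraction(values, mx, my)
        for _ in range(5):
            perm = rng.permutation(15)
            assert concordance_fraction(values[perm], mx, my) == base


class TestShuffleNull:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_permutation_oracle_matches_analytic(self, n):
        """Mean concordance over all n! permutations equals
        (n_hx*n_hy + n_lx*n_ly)/n^2."""
        rng = np.random.default_rng(n)
        values = rng.random((n, 2))
        mx, my = float(np.median(values[:, 0])), float(np.median(values[:, 1]))
        brute = np.mean([
            concordance_fraction(
                np.column_stack([values[:, 0], np.array(perm)]), mx, my)
            for perm in itertools.permutations(values[:, 1])
        ])
        assert brute == pytest.approx(exact_null_mean(values, mx, my), abs=1e-12)

    def test_shuffle_null_converges_to_exact_expectation(self):
        rng = np.random.default_rng(17)
        values = rng.random((20, 2))
        mx, my = float(np.median(values[:, 0])), float(np.median(values[:, 1]))
        null = shuffle_null(values, mx, my, n_shuffles=4000, rng=1)
        assert null == pytest.approx(exact_null_mean(values, mx, my), abs=0.02)

    def test_balanced_even_split_null_is_half(self):
        x = np.array([0.1, 0.2, 0.8, 0.9, 0.3, 0.7])
        values = np.column_stack([x, x])
        mx = my = float(np.median(x))
        assert exact_null_mean(values, mx, my) == pytest.approx(0.5)

    def test_degenerate_y_gives_constant_concordance(self):
        values = np.column_stack([np.linspace(0, 1, 8), np.full(8, 0.3)])
        mx, my = 0.5, 0.3  # all y at the median -> always "low"
        observed = concordance_fraction(values, mx, my)
        assert shuffle_null(values, mx, my, n_shuffles=50, rng=0) == observed

    def test_same_seed_identical_null(self):
        rng = np.random.default_rng(23)
        values = rng.random((30, 2))
        a = shuffle_null(values, 0.5, 0.5, rng=7)
        b = shuffle_null(values, 0.5, 0.5, rng=7)
        assert a == b


class TestPairTable:
    def test_pair_table_reports_pair_with_enough_shared_reads(self):
        rng = np.random.default_rng(2)
        reads = [spanning_read(f"r{i}", rng.random(), rng.random(), n_calls=10)
                 for i in range(30)]
        pairs = cgi_pair_table(reads, [CGI_A, CGI_B], seed=0)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["n_reads"] == 30
        assert row["distance_bp"] == 5000 - 1100
        assert 0 <= row["concordance"] <= 1 and 0 <= row["null_mean"] <= 1

    def test_pairs_below_ten_shared_reads_not_reported(self):
        reads = [spanning_read(f"r{i}", 0.5, 0.5) for i in range(9)]
        assert cgi_pair_table(reads, [CGI_A, CGI_B], min_reads_per_cgi=5).empty

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        reads = [spanning_read(f"r{i}", rng.random(), rng.random(), n_calls=10)
                 for i in range(25)]
        p1 = cgi_pair_table(reads, [CGI_A, CGI_B], seed=11)
        p2 = cgi_pair_table(reads, [CGI_A, CGI_B], seed=11)
        assert p1.equals(p2)
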