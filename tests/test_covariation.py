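"""Covariation statistics against hand values and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oysterlsu.covariation import (
    ColumnPairStat,
    RnaAlignment,
    UninformativeColumn,
    canonical_pair_candidates,
    column_profile,
    covariation_matrix,
    mutual_information,
    pair_chi_square,
    predict_pairs,
)

from conftest import make_alignment


# ---------------------------------------------------------------------------
# Independent oracles: direct evaluation of the defining sums.


def oracle_mi_bits(col_i, col_j):
    rows = [(a, b) for a, b in zip(col_i, col_j) if a != "-" and b != "-"]
    n = len(rows)
    fxy = {}
    for ab in rows:
        fxy[ab] = fxy.get(ab, 0) + 1 / n
    fx, fy = {}, {}
    for (a, b), f in fxy.items():
        fx[a] = fx.get(a, 0) + f
        fy[b] = fy.get(b, 0) + f
    return sum(
        f * math.log2(f / (fx[a] * fy[b])) for (a, b), f in fxy.items()
    )


def oracle_chi2(col_i, col_j):
    rows = [(a, b) for a, b in zip(col_i, col_j) if a != "-" and b != "-"]
    n = len(rows)
    cats_i = sorted({a for a, _ in rows})
    cats_j = sorted({b for _, b in rows})
    if len(cats_i) < 2 or len(cats_j) < 2:
        return 0.0, 0
    chi2 = 0.0
    for a in cats_i:
        for b in cats_j:
            obs = sum(1 for r in rows if r == (a, b))
            exp = (
                sum(1 for x, _ in rows if x == a)
                * sum(1 for _, y in rows if y == b)
                / n
            )
            chi2 += (obs - exp) ** 2 / exp
    return chi2, (len(cats_i) - 1) * (len(cats_j) - 1)


def random_alignment(rng, n_rows, n_cols, gap_rate=0.1):
    letters = np.array(list("ACGU-"))
    p = [0.225, 0.225, 0.225, 0.225, gap_rate]
    p = np.array(p) / sum(p)
    rows = ["".join(rng.choice(letters, size=n_cols, p=p)) for _ in range(n_rows)]
    return make_alignment(*rows)


# ---------------------------------------------------------------------------


class TestColumnProfile:
    def test_constant_column(self):
        aln = make_alignment("AC", "AC", "AC", "AC")
        freqs, gaps = column_profile(aln, 1)
        assert freqs["A"] == 1.0 and gaps == 0

    def test_even_split(self):
        aln = make_alignment("A", "A", "G", "G")
        freqs, _ = column_profile(aln, 1)
        assert freqs["A"] == freqs["G"] == 0.5

    def test_gaps_excluded_from_denominator(self):
        aln = make_alignment("A", "-", "A", "-")
        freqs, gaps = column_profile(aln, 1)
        assert freqs["A"] == 1.0 and gaps == 2

    def test_all_gap_column_flagged(self):
        aln = make_alignment("-A", "-C")
        with pytest.raises(UninformativeColumn):
            column_profile(aln, 1)


class TestHandValues:
    def test_constant_columns_zero_bits(self):
        aln = make_alignment("AU", "AU", "AU", "AU")
        assert mutual_information(aln, 1, 2) == 0.0

    def test_two_state_perfect_covariation_is_one_bit(self):
        aln = make_alignment("AU", "AU", "GC", "GC")
        assert mutual_information(aln, 1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_four_state_perfect_covariation_is_two_bits(self):
        aln = make_alignment("AU", "UA", "GC", "CG", "AU", "UA", "GC", "CG")
        assert mutual_information(aln, 1, 2) == pytest.approx(2.0, abs=1e-12)

    def test_chi2_constant_columns(self):
        aln = make_alignment("AU", "AU", "AU", "AU")
        assert pair_chi_square(aln, 1, 2) == (0.0, 0)

    def test_chi2_perfect_2x2_equals_n(self):
        # 4x AU + 4x GC: every cell's expectation is 2, chi2 = 8 = n, df = 1
        aln = make_alignment(*(["AU"] * 4 + ["GC"] * 4))
        chi2, df = pair_chi_square(aln, 1, 2)
        assert chi2 == pytest.approx(8.0, abs=1e-12)
        assert df == 1

    def test_chi2_independent_columns_vanishes_per_row(self):
        rng = np.random.default_rng(42)
        n = 10_000
        rows = ["".join(rng.choice(["A", "G"], 2)) for _ in range(n)]
        chi2, _ = pair_chi_square(make_alignment(*rows), 1, 2)
        assert chi2 / n < 0.01


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n_rows=10, n_cols=8)
        stats = covariation_matrix(aln, min_n_eff=2)
        assert len(stats) == 8 * 7 // 2
        for s in stats:
            ci, cj = aln.column(s.i), aln.column(s.j)
            if s.mi_bits is None:
                continue
            assert s.mi_bits == pytest.approx(oracle_mi_bits(ci, cj), abs=1e-12)
            chi2, df = oracle_chi2(ci, cj)
            assert s.chi2 == pytest.approx(chi2, abs=1e-12)
            assert s.df == df

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 8, 6)
        perm = rng.permutation(len(aln.rows))
        shuffled = make_alignment(*(aln.rows[k] for k in perm))
        for i, j in itertools.combinations(range(1, 7), 2):
            assert mutual_information(aln, i, j) == pytest.approx(
                mutual_information(shuffled, i, j), abs=1e-12
            )

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mi_bounded_by_column_entropies(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 10, 4, gap_rate=0.0)
        for i, j in itertools.combinations(range(1, 5), 2):
            mi = mutual_information(aln, i, j)
            h_i = mutual_information(aln, i, i)  # MI(i,i) = column entropy
            h_j = mutual_information(aln, j, j)
            assert 0.0 <= mi <= min(h_i, h_j) + 1e-12
            assert mi <= 2.0 + 1e-12


class TestCovariationMatrix:
    def test_pair_count(self):
        aln = make_alignment("ACG", "ACG", "UGC")
        assert len(covariation_matrix(aln, min_n_eff=2)) == 3

    def test_low_n_eff_reported_undefined_not_zero(self):
        aln = make_alignment("A-", "-U", "AU")
        stats = covariation_matrix(aln, min_n_eff=2)
        (s,) = stats
        assert s.n_eff == 1
        assert s.mi_bits is None and s.chi2 is None

    def test_deterministic_ordering(self, structured_alignment):
        stats = covariation_matrix(
            make_alignment("ACG", "AGC", "UCG"), min_n_eff=2
        )
        assert [(s.i, s.j) for s in stats] == [(1, 2), (1, 3), (2, 3)]


class TestPredictPairs:
    def test_no_signal_empty_structure(self):
        aln = make_alignment("AAAA", "AAAA", "AAAA")
        pred = predict_pairs(covariation_matrix(aln, min_n_eff=2))
        assert pred.pairs == frozenset()

    def test_single_dominant_pair(self):
        rows = ["AUCC", "AUCC", "GCCC", "GCCC", "AUCC", "GCCC"]
        pred = predict_pairs(covariation_matrix(make_alignment(*rows), min_n_eff=2))
        assert pred.pairs == {(1, 2)}

    def test_empty_stats(self):
        assert predict_pairs([]).pairs == frozenset()

    def test_canonical_candidate_filter(self):
        # consensus letters A/U can pair, so (1,2) passes the filter
        aln = make_alignment("AU", "AU", "AU", "GC")
        cands = canonical_pair_candidates(aln)
        assert (1, 2) in cands
        pred = predict_pairs(
            covariation_matrix(aln, min_n_eff=2), allow_pairs=cands
        )
        assert pred.pairs == {(1, 2)}

    def test_non_canonical_consensus_filtered(self):
        # consensus A/C cannot pair: the filter drops the column pair even
        # though its covariation signal is perfect
        aln = make_alignment("AC", "AC", "GU", "AC")
        cands = canonical_pair_candidates(aln)
        assert (1, 2) not in cands
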