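"""Covariation metrics: exact endpoints, oracles, and invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevotrace.covariation import (
    Alignment,
    DegenerateAlignmentError,
    EmptyColumnError,
    InsufficientDataError,
    PairScoreTable,
    chi_square_pair,
    column_entropy,
    filter_invariant_columns,
    joint_entropy,
    mi_adj,
    mi_over_joint_entropy,
    mip,
    mutual_information,
    read_external_scores,
    read_fasta,
    score_all_pairs,
    write_fasta,
)

col = lambda s: np.array(list(s), dtype="<U1")  # noqa: E731


class TestEntropy:
    @pytest.mark.parametrize(
        "column, expected",
        [("AAAA", 0.0), ("ABAB", 1.0), ("ABCD", 2.0), ("A-A-", 0.0), ("AB--", 1.0)],
    )
    def test_known_values(self, column, expected):
        assert column_entropy(col(column)) == pytest.approx(expected)

    def test_all_gap_column_rejected(self):
        with pytest.raises(EmptyColumnError):
            column_entropy(col("----"))


class TestMutualInformation:
    def test_identical_even_split_columns_reach_one_bit(self):
        # the theoretical maximum for binary characters
        a = col("00001111")
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_constant_column_gives_zero(self):
        assert mutual_information(col("ABABAB"), col("CCCCCC")) == pytest.approx(0.0)

    def test_factorized_joint_gives_zero(self):
        # every (x, y) combination appears equally often: independence
        a = col("0011" * 2)
        b = col("0101" * 2)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = col("".join(rng.choice(list("ACDE"), 30)))
            b = col("".join(rng.choice(list("ACDE"), 30)))
            mi = mutual_information(a, b)
            assert mi == pytest.approx(mutual_information(b, a), abs=1e-12)
            assert -1e-12 <= mi <= min(column_entropy(a), column_entropy(b)) + 1e-9
            assert mi <= joint_entropy(a, b) + 1e-9

    def test_gap_rows_excluded_pairwise(self):
        # gaps in either column drop the row for this pair only
        a = col("0011-")
        b = col("0101-")
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_complete_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            mutual_information(col("A---"), col("-B--"))


class TestMiOverJointEntropy:
    def test_identical_even_split_is_one(self):
        a = col("0101")
        assert mi_over_joint_entropy(a, a) == pytest.approx(1.0)

    def test_independent_uniform_is_zero(self):
        assert mi_over_joint_entropy(col("0011"), col("0101")) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = col("".join(rng.choice(list("AB"), 20)))
            b = col("".join(rng.choice(list("AB"), 20)))
            if column_entropy(a) == 0 and column_entropy(b) == 0:
                continue
            assert mi_over_joint_entropy(a, b) <= 1 + 1e-12

    def test_double_constant_pair_rejected(self):
        with pytest.raises(DegenerateAlignmentError):
            mi_over_joint_entropy(col("AAAA"), col("BBBB"))


class TestMip:
    def test_uniform_mi_matrix_corrects_to_zero(self):
        m = np.full((5, 5), 0.4)
        np.fill_diagonal(m, 0.0)
        assert np.allclose(mip(m), 0.0, atol=1e-12)

    def test_three_column_hand_oracle(self):
        # brute-force APC over the 3 pairs
        mi = {(0, 1): 0.8, (0, 2): 0.2, (1, 2): 0.4}
        m = np.zeros((3, 3))
        for (i, j), v in mi.items():
            m[i, j] = m[j, i] = v
        col_mean = m.sum(1) / 2
        overall = m.sum() / 6
        expected = {
            pair: v - col_mean[pair[0]] * col_mean[pair[1]] / overall
            for pair, v in mi.items()
        }
        out = mip(m)
        for (i, j), v in expected.items():
            assert out[i, j] == pytest.approx(v, abs=1e-12)

    def test_apc_reduces_background_on_independent_columns(self):
        # over many alignments of independent columns the mean corrected
        # score sits nearer zero than the raw MI background
        rng = np.random.default_rng(11)
        raw_means, corrected_means = [], []
        for _ in range(100):
            matrix = rng.choice(list("AB"), size=(12, 6))
            aln = Alignment([f"s{i}" for i in range(12)], matrix)
            pairs = list(itertools.combinations(range(1, 7), 2))
            m = np.zeros((6, 6))
            for i, j in pairs:
                v = mutual_information(aln.column(i), aln.column(j))
                m[i - 1, j - 1] = m[j - 1, i - 1] = v
            try:
                c = mip(m)
            except DegenerateAlignmentError:
                continue
            raw_means.append(np.mean([m[i - 1, j - 1] for i, j in pairs]))
            corrected_means.append(np.mean([c[i - 1, j - 1] for i, j in pairs]))
        assert abs(np.mean(corrected_means)) < abs(np.mean(raw_means))

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            mip(np.zeros((2, 2)))


class TestMiAdj:
    def test_zero_shuffles_equals_raw_mi(self):
        a, b = col("AABB"), col("ABAB")
        assert mi_adj(a, b, n_shuffles=0) == mutual_information(a, b)

    def test_positive_for_identical_columns(self):
        a = col("0000011111" * 3)
        assert mi_adj(a, a, n_shuffles=200, seed=5) > 0.3

    def test_seed_reproducibility(self):
        a, b = col("AABBABAB"), col("ABABBABA")
        assert mi_adj(a, b, 50, seed=9) == mi_adj(a, b, 50, seed=9)

    def test_negative_shuffles_rejected(self):
        with pytest.raises(ValueError):
            mi_adj(col("AB"), col("AB"), n_shuffles=-1)


class TestChiSquare:
    def test_independent_proportional_table_is_zero(self):
        assert chi_square_pair(col("0011"), col("0101")) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_two_by_two_table(self):
        # counts (10,0;0,10): every expectation is 5, statistic 4*25/5 = 20
        a = col("A" * 10 + "B" * 10)
        assert chi_square_pair(a, a) == pytest.approx(20.0)

    def test_doubling_counts_doubles_statistic(self):
        a, b = col("AABBAB"), col("ABABBA")
        assert chi_square_pair(np.tile(a, 2), np.tile(b, 2)) == pytest.approx(
            2 * chi_square_pair(a, b), abs=1e-9
        )

    def test_agrees_with_scipy_contingency(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(2)
        a = col("".join(rng.choice(list("ABC"), 40)))
        b = col("".join(rng.choice(list("AB"), 40)))
        table = np.zeros((3, 2))
        for x, y in zip(a, b):
            table["ABC".index(x), "AB".index(y)] += 1
        expected = chi2_contingency(table, correction=False).statistic
        assert chi_square_pair(a, b) == pytest.approx(expected, rel=1e-10)


class TestInvariantFilter:
    def test_constant_and_single_residue_columns_removed(self):
        aln = Alignment.from_records(
            [("a", "AAX-"), ("b", "ABX-"), ("c", "AB-A")]
        )
        filtered, kept = filter_invariant_columns(aln)
        # col1 constant, col3 single distinct non-gap, col4 single distinct
        assert kept == [2]
        assert filtered.n_columns == 1

    def test_all_variable_identity_map(self):
        aln = Alignment.from_records([("a", "AB"), ("b", "BA")])
        filtered, kept = filter_invariant_columns(aln)
        assert kept == [1, 2]
        assert np.array_equal(filtered.matrix, aln.matrix)

    def test_idempotent(self):
        aln = Alignment.from_records([("a", "AAB"), ("b", "ABB"), ("c", "AB-")])
        once, kept1 = filter_invariant_columns(aln)
        twice, kept2 = filter_invariant_columns(once)
        assert np.array_equal(once.matrix, twice.matrix)
        assert kept2 == list(range(1, once.n_columns + 1))

    def test_all_invariant_warns_not_raises(self):
        aln = Alignment.from_records([("a", "AA"), ("b", "AA")])
        with pytest.warns(UserWarning):
            filtered, kept = filter_invariant_columns(aln)
        assert kept == [] and filtered.n_columns == 0


class TestExternalScores:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "scores.txt"
        p.write_text("1 5 0.73\n2,6,0.10\n# comment\n\n3 4 1 8.5\n")
        scores = read_external_scores(p, "PSICOV", n_columns=10)
        assert scores == {(1, 5): 0.73, (2, 6): 0.10, (3, 4): 8.5}

    def test_self_pair_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("2 2 0.5\n")
        with pytest.raises(ValueError, match="self-pair"):
            read_external_scores(p, "DI", n_columns=5)

    def test_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 99 0.5\n")
        with pytest.raises(ValueError, match="bounds"):
            read_external_scores(p, "DI", n_columns=5)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2 0.5\nx y z\n")
        with pytest.raises(ValueError, match=":2"):
            read_external_scores(p, "DI", n_columns=5)

    def test_duplicate_last_wins(self, tmp_path, caplog):
        p = tmp_path / "dup.txt"
        p.write_text("1 2 0.5\n2 1 0.9\n")
        import logging

        with caplog.at_level(logging.WARNING):
            scores = read_external_scores(p, "DI", n_columns=5)
        assert scores == {(1, 2): 0.9}
        assert "duplicate" in caplog.text


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        aln = Alignment.from_records([("s1", "AC-G"), ("s2", "A--G")])
        path = tmp_path / "a.fasta"
        write_fasta(aln, path)
        back = read_fasta(path)
        assert back.ids == aln.ids
        assert np.array_equal(back.matrix, aln.matrix)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Alignment.from_records([("a", "AB"), ("b", "ABC")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment.from_records([("a", "AB"), ("a", "BA")])


class TestScoreTable:
    def test_score_all_pairs_and_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        aln = Alignment(
            [f"s{i}" for i in range(10)], rng.choice(list("AB"), size=(10, 5))
        )
        table = score_all_pairs(aln, metrics=("MI", "MIp", "chi2"), seed=1)
        assert len(table.df) == 10  # C(5,2)
        path = tmp_path / "scores.tsv"
        table.to_tsv(path)
        back = PairScoreTable.from_tsv(path, n_columns=5)
        assert np.allclose(
            back.df.sort_index(axis=1).values, table.df.sort_index(axis=1).values
        )

    def test_out_of_bounds_pair_rejected(self):
        table = PairScoreTable.empty(4)
        with pytest.raises(ValueError):
            table.add_metric("MI", {(1, 9): 0.5})


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_chi2_and_mi_vanish_together_on_factorized_tables(seed):
    """chi-square and MI agree on exact independence: both are zero iff the
    joint table factorizes into its marginals."""
    rng = np.random.default_rng(seed)
    a = col("".join(rng.choice(list("AB"), 24)))
    b = col("".join(rng.choice(list("AB"), 24)))
    mi = mutual_information(a, b)
    x2 = chi_square_pair(a, b)
    assert (mi < 1e-12) == (x2 < 1e-9)
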