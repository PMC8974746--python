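"""Smith–Waterman correctness against independent oracles, plus E-values.

The score oracle enumerates every pair of substrings and, for each pair,
every gapped global alignment between them by recursion over alignment
moves — no dynamic programming, no traceback — so it shares nothing with
the implementation under test.  A second, independent cross-check uses
Biopython's PairwiseAligner in local mode with the same matrix and gap
model.
"""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from allerscreen.align import (
    Aligner,
    AlignParams,
    LocalAlignment,
    evalue,
    load_matrix,
    percent_identity,
    smith_waterman,
)
from allerscreen.errors import AlignmentError, ConfigError

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _score_lookup(matrix_name="BLOSUM50"):
    m = load_matrix(matrix_name)
    return {a: {b: int(m[a, b]) for b in m.alphabet} for a in m.alphabet}


def global_affine_best(a, b, sub, gap_open, gap_extend):
    """Best global affine-gap score of two strings by move enumeration."""
    best = -(10**9)

    def rec(i, j, last, acc):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + sub[a[i]][b[j]])
        if i < len(a):
            rec(i + 1, j, "U", acc + (gap_extend if last == "U" else gap_open))
        if j < len(b):
            rec(i, j + 1, "L", acc + (gap_extend if last == "L" else gap_open))

    rec(0, 0, "M", 0)
    return best


def local_score_oracle(q, s, sub, gap_open, gap_extend):
    """Exhaustive local score: max over all substring pairs, floor 0."""
    best = 0
    for i in range(len(q)):
        for j in range(i + 1, len(q) + 1):
            for k in range(len(s)):
                for l in range(k + 1, len(s) + 1):
                    best = max(
                        best,
                        global_affine_best(q[i:j], s[k:l], sub, gap_open, gap_extend),
                    )
    return best


class TestSmithWaterman:
    def test_self_alignment_is_identity(self):
        aln = smith_waterman("HEAGAWGHEE", "HEAGAWGHEE")
        assert aln.identity_fraction == 1.0
        assert aln.n_columns == 10
        assert (aln.q_start, aln.q_end, aln.s_start, aln.s_end) == (1, 10, 1, 10)
        m = load_matrix("BLOSUM50")
        assert aln.score == sum(m[c, c] for c in "HEAGAWGHEE")

    def test_all_mismatch_returns_empty_alignment(self):
        aln = smith_waterman("AAAA", "CCCC")
        assert aln.score == 0
        assert aln.n_columns == 0
        assert aln.is_empty

    def test_score_equals_exhaustive_enumeration_on_small_pairs(self):
        sub = _score_lookup()
        params = AlignParams()
        eng = Aligner(params)
        rng = np.random.default_rng(2024)
        letters = list("ACDE")
        for _ in range(60):
            q = "".join(rng.choice(letters, rng.integers(1, 7)))
            s = "".join(rng.choice(letters, rng.integers(1, 7)))
            expected = local_score_oracle(q, s, sub, params.gap_open, params.gap_extend)
            assert eng.stats(q, s).score == expected, (q, s)

    def test_score_agrees_with_biopython_local_aligner(self):
        from Bio import Align as BA
        from Bio.Align import substitution_matrices

        al = BA.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load("BLOSUM50")
        al.open_gap_score = -10
        al.extend_gap_score = -2
        eng = Aligner()
        rng = np.random.default_rng(7)
        for _ in range(40):
            q = "".join(rng.choice(list(AA20), rng.integers(10, 80)))
            s = "".join(rng.choice(list(AA20), rng.integers(10, 80)))
            assert eng.stats(q, s).score == int(al.score(q, s))

    def test_alignment_column_bookkeeping_is_consistent(self):
        """Recount every alignment column by hand for random pairs."""
        eng = Aligner()
        rng = np.random.default_rng(13)
        for _ in range(50):
            q = "".join(rng.choice(list(AA20), rng.integers(5, 60)))
            s = "".join(rng.choice(list(AA20), rng.integers(5, 60)))
            aln = eng.align(q, s)
            if aln.is_empty:
                continue
            assert not any(a == "-" and b == "-" for a, b in aln.columns)
            assert aln.n_columns == len(aln.columns)
            assert aln.n_identities == sum(
                1 for a, b in aln.columns if a == b and a != "X"
            )
            q_res = [a for a, _ in aln.columns if a != "-"]
            s_res = [b for _, b in aln.columns if b != "-"]
            assert aln.q_end - aln.q_start + 1 == len(q_res)
            assert aln.s_end - aln.s_start + 1 == len(s_res)
            assert "".join(q_res) == q[aln.q_start - 1 : aln.q_end]
            assert "".join(s_res) == s[aln.s_start - 1 : aln.s_end]

    def test_x_never_counts_as_identity(self):
        aln = smith_waterman("AAXAA", "AAXAA")
        assert aln.n_columns == 5
        assert aln.n_identities == 4
        assert aln.identity_fraction < 1.0

    @pytest.mark.parametrize("q,s", [("", "ACD"), ("ACD", "")])
    def test_empty_sequence_raises(self, q, s):
        with pytest.raises(AlignmentError):
            smith_waterman(q, s)

    def test_residue_absent_from_matrix_raises(self):
        with pytest.raises(AlignmentError, match="'U'"):
            smith_waterman("ACU", "ACD")

    @given(st.text(alphabet=AA20, min_size=1, max_size=25),
           st.text(alphabet=AA20, min_size=1, max_size=25))
    def test_score_is_symmetric(self, q, s):
        eng = Aligner()
        assert eng.stats(q, s).score == eng.stats(s, q).score

    @given(st.text(alphabet=AA20, min_size=1, max_size=20),
           st.text(alphabet=AA20, min_size=1, max_size=20),
           st.text(alphabet=AA20, min_size=1, max_size=5))
    def test_appending_residues_never_decreases_local_score(self, q, s, extra):
        eng = Aligner()
        base = eng.stats(q, s).score
        assert eng.stats(q + extra, s).score >= base
        assert eng.stats(q, s + extra).score >= base

    @given(st.text(alphabet=AA20, min_size=1, max_size=40))
    def test_self_alignment_scores_diagonal_sum(self, s):
        eng = Aligner()
        m = load_matrix("BLOSUM50")
        st_ = eng.stats(s, s)
        assert st_.score == sum(m[c, c] for c in s)
        assert st_.n_identities == st_.n_columns == len(s)


class TestPercentIdentity:
    def test_exact_threshold_arithmetic(self):
        cols = [("A", "A")] * 28 + [("A", "C")] * 52
        aln = LocalAlignment(100, 1, 80, 1, 80, cols, 28, 80)
        assert percent_identity(aln) == pytest.approx(0.35)

    def test_gap_free_self_alignment_is_one(self):
        assert percent_identity(smith_waterman("WWWWW", "WWWWW")) == 1.0

    def test_undefined_for_empty_alignment(self):
        with pytest.raises(AlignmentError):
            percent_identity(smith_waterman("AAAA", "CCCC"))

    def test_recount_matches_for_random_alignments(self):
        eng = Aligner()
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(100):
            q = "".join(rng.choice(list(AA20), 30))
            s = "".join(rng.choice(list(AA20), 30))
            aln = eng.align(q, s)
            if aln.is_empty:
                continue
            recount = sum(1 for a, b in aln.columns if a == b and a != "X")
            assert percent_identity(aln) == recount / len(aln.columns)
            checked += 1
        assert checked > 50


class TestEvalue:
    def test_score_zero_gives_k_m_n(self):
        p = AlignParams()
        assert evalue(0, 100, 1000, p) == pytest.approx(p.ka_k * 100 * 1000)

    def test_doubling_database_doubles_evalue(self):
        assert evalue(50, 100, 2000) == pytest.approx(2 * evalue(50, 100, 1000))

    def test_matches_direct_formula_on_grid(self):
        p = AlignParams.for_matrix("BLOSUM62")
        for score in (0, 10, 40, 90):
            for m in (10, 250):
                for n in (100, 10**6):
                    expected = p.ka_k * m * n * math.exp(-p.ka_lambda * score)
                    assert evalue(score, m, n, p) == pytest.approx(expected)

    def test_monotone_decreasing_in_score(self):
        assert evalue(60, 100, 1000) < evalue(40, 100, 1000)

    def test_nonpositive_lengths_raise(self):
        with pytest.raises(AlignmentError):
            evalue(10, 0, 1000)


class TestParams:
    def test_gap_penalty_ordering_enforced(self):
        with pytest.raises(ConfigError):
            AlignParams(gap_open=-2, gap_extend=-10)
        with pytest.raises(ConfigError):
            AlignParams(gap_open=-10, gap_extend=0)

    def test_for_matrix_sets_tabulated_constants(self):
        p = AlignParams.for_matrix("BLOSUM62")
        assert (p.ka_lambda, p.ka_k) == (0.318, 0.134)
        with pytest.raises(ConfigError):
            AlignParams.for_matrix("PAM30")

    def test_unknown_matrix_name_raises(self):
        with pytest.raises(ConfigError):
            load_matrix("NOT_A_MATRIX")
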