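import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

import sasearch as ss
from sasearch.align import score_alignment, smith_waterman_score


class TestLoadMatrix:
    def test_blosum62_entries(self, scheme):
        assert scheme.score("W", "W") == 11
        assert scheme.score("A", "A") == 4
        assert scheme.name == "BLOSUM62"
        assert (scheme.gap_open, scheme.gap_extend) == (11, 1)
        assert (scheme.lam, scheme.K) == (0.267, 0.041)

    @pytest.mark.parametrize("name", ["BLOSUM45", "BLOSUM80"])
    def test_other_bundled_matrices(self, name):
        sch = ss.load_matrix(name)
        assert np.array_equal(sch.matrix, sch.matrix.T)
        assert sch.lam > 0 and sch.K > 0

    def test_custom_file_requires_lambda_k(self, tmp_path):
        path = tmp_path / "custom.mat"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        with pytest.raises(ValueError, match="lambda and K"):
            ss.load_matrix(path)
        sch = ss.load_matrix(path, lam=0.267, K=0.041)
        assert sch.score("A", "A") == 4

    def test_missing_residue_named(self, tmp_path):
        arr = substitution_matrices.load("BLOSUM62")
        no_x = arr.select("ACDEFGHIKLMNPQRSTVWY")
        path = tmp_path / "nox.mat"
        path.write_text(str(no_x))
        with pytest.raises(ValueError, match="X"):
            ss.load_matrix(path, lam=0.267, K=0.041)

    def test_unknown_name(self):
        with pytest.raises(FileNotFoundError):
            ss.load_matrix("PAM999")


def random_pair(rng, related, max_len=120):
    a = ss.random_protein(int(rng.integers(5, max_len + 1)), rng)
    if related:
        b = ss.mutate_homolog(a, float(rng.uniform(0.3, 0.9)), rng)
    else:
        b = ss.random_protein(int(rng.integers(5, max_len + 1)), rng)
    return a, b


class TestBandedAlign:
    def test_identical_sequences_score_diagonal_sum(self, scheme):
        aln = ss.banded_align("ACDEFG", "ACDEFG", 0, 8, scheme)
        assert aln.score == sum(scheme.score(c, c) for c in "ACDEFG")
        assert aln.identity == 1.0
        assert (aln.q_start, aln.q_end) == (0, 6)

    def test_all_negative_pair_gives_empty_alignment(self, scheme):
        aln = ss.banded_align("AAAA", "WWWW", 0, 8, scheme)
        assert aln.score == 0
        assert aln.query_aligned == "" and aln.target_aligned == ""

    def test_band_excluding_matrix_gives_empty(self, scheme):
        aln = ss.banded_align("ACDE", "ACDE", 100, 2, scheme)
        assert aln.score == 0

    def test_matches_unbanded_oracle(self, scheme, reference_aligner, rng):
        for k in range(60):
            a, b = random_pair(rng, related=bool(k % 2))
            hb = max(len(a), len(b))
            aln = ss.banded_align(a, b, 0, hb, scheme)
            assert aln.score == int(reference_aligner.score(a, b))

    def test_score_nondecreasing_in_half_band(self, scheme, rng):
        for _ in range(10):
            a, b = random_pair(rng, related=True, max_len=80)
            prev = -1
            for hb in (1, 2, 4, 8, 16, 32, 64, 128):
                s = ss.banded_align(a, b, 0, hb, scheme).score
                assert s >= prev
                prev = s
            assert prev == int(smith_waterman_score(a, b, scheme))

    def test_rescoring_and_interval_consistency(self, scheme, rng):
        for k in range(40):
            a, b = random_pair(rng, related=bool(k % 2))
            aln = ss.banded_align(a, b, 0, max(len(a), len(b)), scheme)
            if aln.score == 0:
                continue
            assert score_alignment(aln.query_aligned, aln.target_aligned,
                                   scheme) == aln.score
            assert aln.query_aligned.replace("-", "") == a[aln.q_start:aln.q_end]
            assert aln.target_aligned.replace("-", "") == b[aln.t_start:aln.t_end]
            assert len(aln.query_aligned) == len(aln.target_aligned)

    def test_full_dp_scorer_matches_oracle(self, scheme, reference_aligner, rng):
        """The score-only unbanded kernel used for TRUE-set construction
        agrees with the independent aligner."""
        for k in range(60):
            a, b = random_pair(rng, related=bool(k % 3 == 0))
            assert smith_waterman_score(a, b, scheme) == \
                int(reference_aligner.score(a, b))


class TestEvalue:
    def test_closed_form_example(self):
        sch = ss.ScoringScheme("t", ss.default_scheme().matrix, 11, 1,
                               lam=0.267, K=0.041)
        assert ss.evalue(50, 100, 1000, sch) == pytest.approx(6.5e-3, rel=0.01)

    def test_zero_score_is_kmn(self, scheme):
        assert ss.evalue(0, 123, 4567, scheme) == \
            pytest.approx(scheme.K * 123 * 4567)

    @given(
        m=st.integers(1, 10_000),
        n=st.integers(1, 10_000_000),
        s=st.integers(0, 300),
    )
    def test_linearity_and_monotonicity(self, m, n, s):
        scheme = ss.default_scheme()
        e = ss.evalue(s, m, n, scheme)
        assert e == pytest.approx(scheme.K * m * n * math.exp(-scheme.lam * s))
        assert ss.evalue(s, 2 * m, n, scheme) == pytest.approx(2 * e)
        assert ss.evalue(s, m, 3 * n, scheme) == pytest.approx(3 * e)
        assert ss.evalue(s + 1, m, n, scheme) < e


class TestSchemeValidation:
    def test_asymmetric_matrix_rejected(self, scheme):
        m = scheme.matrix.copy()
        m[0, 1] += 1
        with pytest.raises(ValueError, match="symmetric"):
            ss.ScoringScheme("bad", m, 11, 1, 0.267, 0.041)

    def test_gap_ordering_enforced(self, scheme):
        with pytest.raises(ValueError):
            ss.ScoringScheme("bad", scheme.matrix, 1, 11, 0.267, 0.041)
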