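"""String metrics vs exhaustive oracles, segment extraction, and the MC null."""

import itertools

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctionlab.errors import DegenerateTestError, ValidationError
from junctionlab.seq_core import DeletionCall, GenomeInterval, ReferenceSequence, reverse_complement
from junctionlab.similarity_null import (
    batch_hamming,
    batch_lcs,
    batch_lcseq,
    batch_levenshtein,
    build_null,
    cohort_pvalue,
    cohort_similarity,
    extract_flank_quartet,
    extract_root_pair,
    flag_outliers,
    hamming,
    lcs_substring,
    lcseq,
    levenshtein,
    quartet_similarity,
)
from junctionlab.synthetic_cohort import generate_cohort, random_dna

dna_pair = st.tuples(
    st.text(alphabet="ACGT", min_size=0, max_size=30),
    st.text(alphabet="ACGT", min_size=0, max_size=30),
)


# --- independent oracles ----------------------------------------------------

def oracle_lcs(a, b):
    subs = {a[i:j] for i in range(len(a)) for j in range(i + 1, len(a) + 1)}
    return max((len(s) for s in subs if s in b), default=0)


def oracle_lcseq(a, b):
    def subseqs(s):
        out = set()
        for r in range(len(s) + 1):
            for comb in itertools.combinations(s, r):
                out.add("".join(comb))
        return out

    common = subseqs(a) & subseqs(b)
    return max(len(s) for s in common)


def oracle_levenshtein_recursive(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    return min(
        oracle_levenshtein_recursive(a[1:], b) + 1,
        oracle_levenshtein_recursive(a, b[1:]) + 1,
        oracle_levenshtein_recursive(a[1:], b[1:]) + cost,
    )


class TestMetricExamples:
    def test_lcs_known_value(self):
        assert lcs_substring("ACGTAC", "GTACGG") == 4  # GTAC

    def test_lcs_identity_and_empty(self):
        s = "ACGTACGT"
        assert lcs_substring(s, s) == len(s)
        assert lcs_substring(s, "") == 0

    def test_lcseq_examples(self):
        assert lcseq("ACGT", "AGT") == 3
        assert lcseq("AACG", "GCAA") == oracle_lcseq("AACG", "GCAA") == 2

    def test_levenshtein_examples(self):
        assert levenshtein("ACGT", "ACG") == 1
        assert levenshtein("ACGT", "ACGT") == 0

    def test_hamming_examples(self):
        assert hamming("ACGT", "TGCA") == 4
        assert hamming("ACGT", "ACGT") == 0
        with pytest.raises(ValidationError):
            hamming("AAA", "AAAA")

    def test_n_matches_nothing(self):
        assert hamming("NN", "NN") == 2
        assert lcs_substring("ANG", "ANG") == 1
        assert lcseq("ANG", "ANG") == 2
        assert levenshtein("AN", "AN") == 1


class TestOracleEquivalence:
    def test_two_letter_alphabet_exhaustive(self):
        # ties are stressed on a reduced alphabet; lengths 0..4 exhaustively
        strings = [
            "".join(t)
            for n in range(0, 5)
            for t in itertools.product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                assert lcs_substring(a, b) == oracle_lcs(a, b)
                assert lcseq(a, b) == oracle_lcseq(a, b)
                if a and b:  # edlib is the independent edit-distance oracle
                    assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]
                if len(a) == len(b) and a:
                    assert hamming(a, b) == sum(x != y for x, y in zip(a, b))

    def test_levenshtein_against_plain_recursion(self):
        rng = np.random.default_rng(50)
        for _ in range(60):
            a = random_dna(int(rng.integers(1, 8)), seed=rng)
            b = random_dna(int(rng.integers(1, 8)), seed=rng)
            assert levenshtein(a, b) == oracle_levenshtein_recursive(a, b)

    @settings(max_examples=300, derandomize=True)
    @given(dna_pair)
    def test_metric_axioms(self, pair):
        a, b = pair
        assert lcs_substring(a, b) == lcs_substring(b, a)
        assert lcseq(a, b) == lcseq(b, a)
        assert levenshtein(a, b) == levenshtein(b, a)
        assert lcs_substring(a, b) <= lcseq(a, b) <= min(len(a), len(b))
        assert levenshtein(a, b) >= abs(len(a) - len(b))
        if len(a) == len(b):
            h = hamming(a, b)
            assert hamming(b, a) == h
            assert levenshtein(a, b) <= h

    @settings(max_examples=100, derandomize=True)
    @given(dna_pair, st.text(alphabet="ACGT", max_size=30))
    def test_triangle_inequality(self, pair, c):
        a, b = pair
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)
        if len(a) == len(b) == len(c):
            assert hamming(a, c) <= hamming(a, b) + hamming(b, c)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(60)
        n, w = 50, 25
        A = rng.integers(0, 4, size=(n, w), dtype=np.int8)
        B = rng.integers(0, 4, size=(n, w), dtype=np.int8)
        dec = lambda row: "".join("ACGT"[i] for i in row)
        for i in range(n):
            a, b = dec(A[i]), dec(B[i])
            assert batch_lcs(A, B)[i] == lcs_substring(a, b)
            assert batch_lcseq(A, B)[i] == lcseq(a, b)
            assert batch_levenshtein(A, B)[i] == levenshtein(a, b)
            assert batch_hamming(A, B)[i] == hamming(a, b)


class TestSegments:
    def test_quartet_definitions(self):
        R = random_dna(500, seed=81)
        ref = ReferenceSequence("c", R)
        call = DeletionCall("X", GenomeInterval("c", 100, 400))
        q = extract_flank_quartet(ref, call)
        assert q.A == R[50:100] and q.A1 == R[100:150]
        assert q.B == R[350:400] and q.B1 == R[400:450]
        # A1 and B are inside the deleted interval
        assert R.index(q.A1) >= 100 and R.index(q.B) < 400

    def test_truncation_flag(self):
        ref = ReferenceSequence("c", random_dna(500, seed=82))
        q = extract_flank_quartet(ref, DeletionCall("X", GenomeInterval("c", 10, 400)))
        assert q.truncated and len(q.A) == 10

    def test_quartet_similarity_identity_and_composition(self):
        R = random_dna(500, seed=83)
        ref = ReferenceSequence("c", R)
        q = extract_flank_quartet(ref, DeletionCall("X", GenomeInterval("c", 100, 400)))
        vectors = quartet_similarity(q)
        assert set(vectors) == {"A-A1", "B-B1", "A-B", "A-B1", "A1-B", "A1-B1"}
        v = vectors["A-B1"]
        assert v.lcs == lcs_substring(q.A, q.B1)
        assert v.hamming == hamming(q.A, q.B1)

    def test_planted_copy_with_substitutions(self):
        R = list(random_dna(500, seed=84))
        # make A1 a copy of A with 5 substitutions
        A = R[50:100]
        copy = A.copy()
        for idx in (3, 13, 23, 33, 43):
            copy[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[idx]]
        R[100:150] = copy
        ref = ReferenceSequence("c", "".join(R))
        q = extract_flank_quartet(ref, DeletionCall("X", GenomeInterval("c", 100, 400)))
        assert quartet_similarity(q, ["A-A1"])["A-A1"].hamming == 5

    def test_root_pair_perfect_stem(self):
        # reference where the 30 bp upstream of e is the exact revcomp of the
        # 30 bp downstream of s: root pair becomes two identical strings
        w = 30
        R = list(random_dna(600, seed=85))
        s, e = 200, 400
        R[e - w : e] = reverse_complement("".join(R[s : s + w]))
        ref = ReferenceSequence("c", "".join(R))
        call = DeletionCall("X", GenomeInterval("c", s, e))
        first, second, truncated = extract_root_pair(ref, call, w)
        assert first == second and not truncated
        assert hamming(first, second) == 0
        assert lcs_substring(first, second) == 30

    def test_root_pair_lengths_and_complement_mode(self):
        ref = ReferenceSequence("c", random_dna(600, seed=86))
        call = DeletionCall("X", GenomeInterval("c", 200, 400))
        first, second, _ = extract_root_pair(ref, call, 10)
        assert len(first) == len(second) == 10
        _, lits, _ = extract_root_pair(ref, call, 10, orientation="complement")
        # literal complement is the reversal of the reverse complement
        assert lits == second[::-1]


class TestNull:
    def test_reproducible_and_substream_stable(self):
        a = build_null(("hamming",), (20, 30), n_pairs=500, seed=5)
        b = build_null(("hamming",), (20, 30), n_pairs=500, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.samples, y.samples)
        # adding a window does not change the draws of existing windows
        c = build_null(("hamming",), (10, 20, 30), n_pairs=500, seed=5)
        by_w = {d.window_length: d for d in c}
        assert np.array_equal(by_w[20].samples, a[0].samples)
        assert np.array_equal(by_w[30].samples, a[1].samples)

    def test_hamming_analytic_anchor(self):
        for null in build_null(("hamming",), (10, 20, 30, 100), n_pairs=4000, seed=3):
            se = null.sd / np.sqrt(null.n_pairs)
            assert abs(null.mean - 0.75 * null.window_length) < 3 * se

    def test_single_pair_sd_convention(self):
        (null,) = build_null(("hamming",), (10,), n_pairs=1, seed=1)
        assert null.sd == 0.0

    def test_doubling_pairs_moves_mean_little(self):
        (a,) = build_null(("lcs",), (10,), n_pairs=2000, seed=9)
        (b,) = build_null(("lcs",), (10,), n_pairs=4000, seed=10)
        se = a.sd / np.sqrt(a.n_pairs)
        assert abs(a.mean - b.mean) < 4 * se


class TestFlagsAndPvalues:
    def test_published_outlier_cell(self):
        # a value of 3 against a null of 6.56 +/- 1.18 sits beyond 3 SD
        (null,) = build_null(("hamming",), (10,), n_pairs=100, seed=1)
        null.mean, null.sd = 6.56, 1.18
        z, tier = flag_outliers(3, null)
        assert z == pytest.approx(-3.0169, abs=1e-3)
        assert tier == "beyond3"

    def test_tier_boundaries(self):
        (null,) = build_null(("hamming",), (10,), n_pairs=100, seed=1)
        null.mean, null.sd = 10.0, 2.0
        assert flag_outliers(10.0, null)[1] == "none"
        assert flag_outliers(15.0, null)[1] == "beyond2"
        assert flag_outliers(17.0, null)[1] == "beyond3"

    def test_zero_sd_rejected(self):
        (null,) = build_null(("hamming",), (10,), n_pairs=1, seed=1)
        with pytest.raises(DegenerateTestError):
            flag_outliers(5, null)

    def test_extreme_shift_is_significant(self):
        (null,) = build_null(("hamming",), (20,), n_pairs=2000, seed=2)
        shifted = null.samples[:22] + 10 * null.sd
        assert cohort_pvalue(shifted, null.samples) < 1e-6

    def test_degenerate_groups_rejected(self):
        with pytest.raises(DegenerateTestError):
            cohort_pvalue([3.0, 3.0], [3.0, 3.0, 3.0])

    def test_permutation_agrees_with_welch_in_order_of_magnitude(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 200)
        pw = cohort_pvalue(x, y)
        pp = cohort_pvalue(x, y, method="permutation", n_permutations=2000, seed=1)
        assert (pw > 0.05) == (pp > 0.05)


class TestCohortSimilarity:
    def test_report_shape_and_consistency(self):
        cohort = generate_cohort(6, seed=40)
        rep = cohort_similarity(
            cohort.reference, cohort.calls, window_lengths=(10, 20), n_pairs=300, seed=7
        )
        assert len(rep.per_sample) == 6
        key = ("hamming", 20)
        values = [v[key] for v in rep.per_sample.values()]
        assert rep.cohort_mean[key] == pytest.approx(np.mean(values))
        assert 0.0 <= rep.p_values[key] <= 1.0
        for flags in rep.z_flags.values():
            z, tier = flags[key]
            assert tier in {"none", "beyond2", "beyond3"}
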