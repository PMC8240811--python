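"""Junction microhomology, consensus resolution, and mechanism classification."""

import numpy as np
import pytest

from junctionlab.errors import UnresolvableJunctionError, ValidationError
from junctionlab.junction_mech import (
    JunctionCall,
    Mechanism,
    classify_mechanism,
    find_insertion_template,
    microhomology_from_coordinates,
    resolve_junction,
    summarize_mechanisms,
)
from junctionlab.seq_core import DeletionCall, GenomeInterval, ReferenceSequence
from junctionlab.synthetic_cohort import plant_deletion, random_dna


def junction_slide_oracle(R: str, s: int, e: int) -> tuple[int, int]:
    """Brute force: count breakpoint placements yielding the same joined string.

    Returns (left shifts, right shifts) such that deleting [s+d, e+d) for any
    d in [-left, right) gives the identical junction sequence.
    """
    joined = R[:s] + R[e:]
    right = 0
    while s + right < e and e + right < len(R) and R[: s + right + 1] + R[e + right + 1 :] == joined:
        right += 1
    left = 0
    while s - left > 0 and e - left > s and R[: s - left - 1] + R[e - left - 1 :] == joined:
        left += 1
    return left, right


class TestMicrohomologyFromCoordinates:
    def test_planted_repeat_gives_right_run(self):
        # CGT repeated right after both breakpoints
        R = "AAAA" + "CGT" + "TTGGA" + "CGT" + "AAAA"
        ref = ReferenceSequence("c", R)
        s, e = 4, 12  # deletes "CGTTTGGA"; R[4:7]=CGT == R[12:15]=CGT
        jc = microhomology_from_coordinates(ref, GenomeInterval("c", s, e))
        assert jc.mh_right >= 3

    def test_all_flanks_differ(self):
        ref = ReferenceSequence("c", "CCCCA" + "GGGG" + "TAAAA")
        jc = microhomology_from_coordinates(ref, GenomeInterval("c", 5, 9))
        assert (jc.mh_left, jc.mh_right, jc.mh_total) == (0, 0, 0)

    def test_matches_slide_oracle_on_random_references(self):
        rng = np.random.default_rng(77)
        for trial in range(500):
            n = int(rng.integers(40, 200))
            R = random_dna(n, seed=rng)
            s = int(rng.integers(5, n // 2))
            e = int(rng.integers(s + 2, n - 5))
            jc = microhomology_from_coordinates(ReferenceSequence("c", R), GenomeInterval("c", s, e))
            left, right = junction_slide_oracle(R, s, e)
            assert (jc.mh_left, jc.mh_right) == (left, right), (trial, R, s, e)

    def test_shift_invariance_within_ambiguity_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            R = random_dna(150, seed=rng)
            s, e = 40, 90
            jc = microhomology_from_coordinates(ReferenceSequence("c", R), GenomeInterval("c", s, e))
            joined = R[:s] + R[e:]
            for d in range(-jc.mh_left, jc.mh_right + 1):
                assert R[: s + d] + R[e + d :] == joined

    def test_n_never_matches(self):
        ref = ReferenceSequence("c", "AAAAN" + "GGGG" + "NAAAA")
        jc = microhomology_from_coordinates(ref, GenomeInterval("c", 5, 9))
        assert jc.mh_total == 0


class TestResolveJunction:
    def test_consensus_reproduces_coordinate_scan(self, small_reference):
        rng = np.random.default_rng(15)
        for _ in range(30):
            s = int(rng.integers(300, 700))
            e = int(rng.integers(s + 100, 1500))
            coord = microhomology_from_coordinates(small_reference, GenomeInterval("c", s, e))
            consensus = small_reference.seq[s - 200 : s] + small_reference.seq[e : e + 200]
            call = DeletionCall("X", GenomeInterval("chrT", s, e), junction_consensus=consensus)
            jc = resolve_junction(small_reference, call)
            assert (jc.mh_left, jc.mh_right) == (coord.mh_left, coord.mh_right)
            assert jc.inserted_seq == ""

    def test_planted_microhomology_round_trip(self, small_reference):
        ref, call, truth = plant_deletion(small_reference, 600, 800, microhomology=4, seed=1)
        jc = resolve_junction(ref, call)
        assert jc.mh_total == 4 and jc.inserted_seq == ""

    def test_seven_bp_templated_insertion_is_aror(self, small_reference):
        ref, call, _ = plant_deletion(
            small_reference, 600, 800, insertion_length=7, insertion_template_offset=-30, seed=4
        )
        jc = resolve_junction(ref, call)
        assert len(jc.inserted_seq) == 7
        assert jc.mechanism is Mechanism.AROR
        assert any(s.interval.start == 570 for s in jc.insertion_sources)

    def test_left_flank_only_is_unresolvable(self, small_reference):
        call = DeletionCall(
            "X", GenomeInterval("chrT", 600, 1400),
            junction_consensus=small_reference.seq[400:600],
        )
        with pytest.raises(UnresolvableJunctionError, match="right flank"):
            resolve_junction(small_reference, call)

    def test_without_consensus_falls_back_to_coordinates(self, small_reference):
        call = DeletionCall("X", GenomeInterval("chrT", 600, 1400))
        jc = resolve_junction(small_reference, call)
        ref_jc = microhomology_from_coordinates(small_reference, call)
        assert (jc.mh_left, jc.mh_right) == (ref_jc.mh_left, ref_jc.mh_right)


class TestClassification:
    @pytest.mark.parametrize(
        "mh,ins_len,expected",
        [
            (0, 0, Mechanism.NHEJ),
            (1, 0, Mechanism.NHEJ),
            (2, 0, Mechanism.MMEJ),
            (7, 0, Mechanism.MMEJ),
            (20, 0, Mechanism.MMEJ),
            (21, 0, Mechanism.EXTENSIVE_HOMOLOGY),
            (0, 1, Mechanism.AROR),
            (0, 7, Mechanism.AROR),
            (0, 10, Mechanism.AROR),
            (0, 11, Mechanism.LARGE_INSERTION),
        ],
    )
    def test_signature_table(self, mh, ins_len, expected):
        call = JunctionCall(
            "X", 0, mh, "A" * ins_len, GenomeInterval("c", 10, 10 + max(mh, 1))
        )
        assert classify_mechanism(call) is expected

    def test_partition_is_total_and_unique(self):
        for mh in range(0, 30):
            for ins in range(0, 15):
                if ins and mh:
                    continue  # excluded by the junction-call invariant
                call = JunctionCall("X", 0, mh, "A" * ins, GenomeInterval("c", 5, 6 + mh))
                assert classify_mechanism(call) in Mechanism

    def test_summary_matches_published_arithmetic(self):
        calls = (
            [JunctionCall(f"n{i}", 0, 0, "", GenomeInterval("c", 5, 6)) for i in range(8)]
            + [JunctionCall(f"m{i}", 1, 2, "", GenomeInterval("c", 5, 8)) for i in range(13)]
            + [JunctionCall("a0", 0, 0, "ACGTACG", GenomeInterval("c", 5, 6))]
        )
        for c in calls:
            c.mechanism = classify_mechanism(c)
        summary = summarize_mechanisms(calls)
        assert summary.percentages["NHEJ"] == 36.4
        assert summary.percentages["MMEJ"] == 59.1
        assert summary.percentages["AROR"] == 4.5

    def test_single_call_is_hundred_percent(self):
        call = JunctionCall("X", 0, 3, "", GenomeInterval("c", 5, 8))
        call.mechanism = classify_mechanism(call)
        summary = summarize_mechanisms([call])
        assert summary.percentages["MMEJ"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_mechanisms([])


class TestInsertionTemplate:
    def test_absent_sequence_gives_empty_list(self, small_reference):
        call = DeletionCall("X", GenomeInterval("chrT", 600, 1400))
        # 12-mer very unlikely in 2 kb; construct one absent by checking
        probe = "ACGTACGTACGT"
        while probe in small_reference.seq:
            probe = probe + "A"
        assert find_insertion_template(small_reference, call, probe) == []

    def test_palindromic_insert_reported_on_both_strands(self):
        R = "C" * 300 + "GAATTC" + "C" * 100 + "G" * 200 + "C" * 300
        ref = ReferenceSequence("c", R)
        call = DeletionCall("X", GenomeInterval("c", 350, 700))
        hits = find_insertion_template(ref, call, "GAATTC")
        strands = {(h.interval.start, h.strand) for h in hits if h.breakpoint == "start"}
        assert (300, "+") in strands and (300, "-") in strands

    def test_short_insert_rejected(self, small_reference):
        call = DeletionCall("X", GenomeInterval("chrT", 600, 1400))
        with pytest.raises(ValidationError):
            find_insertion_template(small_reference, call, "AC")
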