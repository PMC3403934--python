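import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from retroscape import synthetic_data as sd
from retroscape._seq import decode, encode
from retroscape.indel_profiling import (
    DiagnosticIndel,
    Scoring,
    accumulate_profile,
    alignment_score,
    call_overrepresented_indels,
    needleman_wunsch_align,
)

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestAligner:
    def test_identity_has_no_ops(self):
        al = needleman_wunsch_align("ACGT", "ACGT")
        assert al.ops == [] and al.score == 4 * Scoring().match

    def test_single_deletion_placed_leftmost(self):
        al = needleman_wunsch_align("AAA", "AAAA")
        (op,) = al.ops
        assert (op.kind, op.position, op.length) == ("deletion", 1, 1)

    def test_single_insertion_placed_leftmost(self):
        al = needleman_wunsch_align("AAAA", "AAA")
        (op,) = al.ops
        assert (op.kind, op.position, op.length) == ("insertion", 0, 1)

    def test_planted_insertion_recovered_exactly(self, rng):
        cons = "".join("ACGT"[c] for c in rng.integers(0, 4, 60))
        ins = "TTTCGGA"
        copy = cons[:33] + ins + cons[33:]
        al = needleman_wunsch_align(copy, cons)
        assert al.score == _oracles.memoized_optimum(copy, cons)
        ins_ops = [op for op in al.ops if op.kind == "insertion"]
        assert any(op.length == 7 and abs(op.position - 33) <= 2 for op in ins_ops)

    def test_score_matches_brute_force_on_tiny_pairs(self, rng):
        for _ in range(50):
            a = "".join("ACGT"[c] for c in rng.integers(0, 4, rng.integers(1, 7)))
            b = "".join("ACGT"[c] for c in rng.integers(0, 4, rng.integers(1, 7)))
            al = needleman_wunsch_align(a, b)
            expected = _oracles.brute_force_optimum(a, b)
            assert al.score == pytest.approx(expected)
            assert _oracles.memoized_optimum(a, b) == pytest.approx(expected)
            assert _oracles.biopython_score(a, b) == pytest.approx(expected)

    def test_n_bases_score_zero(self):
        al = needleman_wunsch_align("ANGT", "ACGT")
        assert al.score == 3 * Scoring().match
        assert al.ops == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch_align("", "ACGT")

    @settings(max_examples=60, deadline=None)
    @given(a=SEQ, b=SEQ)
    def test_emitted_alignment_reproduces_dp_score(self, a, b):
        al = needleman_wunsch_align(a, b)
        assert alignment_score(al.aligned_copy, al.aligned_consensus) == pytest.approx(al.score)
        assert al.aligned_copy.replace("-", "") == a
        assert al.aligned_consensus.replace("-", "") == b

    def test_leftmost_artifact_shift(self, rng):
        # When the last base of an inserted segment equals the consensus
        # base just before the insertion point, leftmost gap placement
        # slides the recorded position upstream of the true one — the
        # well-known secondary-peak artifact of automated indel profiling.
        cons = "".join("ACGT"[c] for c in rng.integers(0, 4, 140))
        cons = cons[:79] + "A" + cons[80:]  # consensus position 80 is A
        ins = "GGGGGGA"  # last base matches consensus base 80
        copy = cons[:80] + ins + cons[80:]
        al = needleman_wunsch_align(copy, cons)
        ins_ops = [op for op in al.ops if op.kind == "insertion" and op.length == 7]
        assert ins_ops and ins_ops[0].position < 80


def _aligned_copies(consensus, copies):
    return [
        needleman_wunsch_align(seq, consensus, copy_id=f"c{i}", family="FAM")
        for i, seq in enumerate(copies)
    ]


class TestProfile:
    CONS = "ACGTACGTACGT" * 10  # 120 nt

    def test_empty_profile(self):
        prof = accumulate_profile([])
        assert prof.n_copies == 0 and prof.ins_count.sum() == 0

    def test_shared_insertion_counted_per_copy(self):
        ins = "TTTCTGA"
        copies = [self.CONS[:80] + ins + self.CONS[80:]] * 10
        prof = accumulate_profile(_aligned_copies(self.CONS, copies))
        assert prof.ins_count[80] == 10
        assert prof.ins_count.sum() == 10
        assert prof.del_count.sum() == 0

    def test_deletion_covers_positions(self):
        copies = [self.CONS[:4] + self.CONS[7:]]  # delete consensus 5..7
        prof = accumulate_profile(_aligned_copies(self.CONS, copies))
        covered = np.nonzero(prof.del_count)[0]
        assert len(covered) == 3 and prof.del_count[covered].tolist() == [1, 1, 1]

    def test_additive_and_permutation_invariant(self, rng):
        copies = []
        for _ in range(12):
            s = list(self.CONS)
            for p in rng.choice(len(s), size=5, replace=False):
                s[p] = "ACGT"[rng.integers(0, 4)]
            copies.append("".join(s))
        als = _aligned_copies(self.CONS, copies)
        full = accumulate_profile(als)
        part = accumulate_profile(als[:5])
        rest = accumulate_profile(als[5:])
        assert np.array_equal(full.ins_count, part.ins_count + rest.ins_count)
        assert np.array_equal(full.del_count, part.del_count + rest.del_count)
        perm = accumulate_profile(als[::-1])
        assert np.array_equal(full.ins_count, perm.ins_count)

    def test_mixed_families_rejected(self):
        a = needleman_wunsch_align("ACGT", "ACGT", family="A")
        b = needleman_wunsch_align("ACGT", "ACGT", family="B")
        with pytest.raises(ValueError, match="mixed"):
            accumulate_profile([a, b])


class TestCalls:
    CONS = "ACGTACGTACGT" * 10

    def _profile(self, n_with_ins=90, n_plain=10):
        ins = "TTTCTGA"
        copies = [self.CONS[:80] + ins + self.CONS[80:]] * n_with_ins + [self.CONS] * n_plain
        return accumulate_profile(_aligned_copies(self.CONS, copies))

    def test_dominant_insertion_called_with_modal_length(self):
        calls = call_overrepresented_indels(self._profile(), min_fraction=0.05)
        (call,) = calls
        assert call.kind == "insertion"
        assert call.consensus_position == 80 and call.length == 7

    def test_min_fraction_one_keeps_only_universal(self):
        assert call_overrepresented_indels(self._profile(90, 10), min_fraction=1.0) == []
        assert len(call_overrepresented_indels(self._profile(100, 0), min_fraction=1.0)) == 1

    def test_low_noise_not_called(self, rng):
        # isolated 1%-frequency indels stay below a 5% threshold
        copies = [self.CONS] * 99 + [self.CONS[:50] + "T" + self.CONS[50:]]
        prof = accumulate_profile(_aligned_copies(self.CONS, copies))
        assert call_overrepresented_indels(prof, min_fraction=0.05) == []

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            call_overrepresented_indels(accumulate_profile([]), 0.05)

    def test_planted_insertion_position_recovered_under_divergence(self):
        # mutated copies still yield the planted insertion at +-2
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            cons = "".join("ACGT"[c] for c in rng.integers(0, 4, 140))
            ins = "TCAGGCT"
            copies = []
            for _ in range(20):
                codes, _ = sd.evolve_sequence(
                    encode(cons[:80] + ins + cons[80:]),
                    1.0, 0.15, 4.0, 0.5, 1.0, rng,
                )
                copies.append(decode(codes))
            prof = accumulate_profile(_aligned_copies(cons, copies))
            calls = call_overrepresented_indels(prof, min_fraction=0.5)
            ins_calls = [c for c in calls if c.kind == "insertion"]
            if ins_calls:
                top = max(ins_calls, key=lambda c: prof.ins_count[c.consensus_position])
                hits += abs(top.consensus_position - 80) <= 2
        assert hits / n_rep >= 0.95


def test_diagnostic_indel_matching_tolerances():
    d = DiagnosticIndel("F", "insertion", 80, 7, position_tolerance=5, length_tolerance=2)
    from retroscape.indel_profiling import IndelOp

    assert d.matches(IndelOp(77, "insertion", 9))
    assert not d.matches(IndelOp(70, "insertion", 7))
    assert not d.matches(IndelOp(80, "deletion", 7))
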