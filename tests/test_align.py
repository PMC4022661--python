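import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilecall import simulate
from tilecall.align import (
    AlignedRead,
    align_insert,
    align_reads,
    assign_read,
    on_target_rate,
    trim_primers,
)
from tilecall.panel import revcomp
from tilecall.simulate import SimulatedRead

from conftest import hand_amplicon, hand_design, random_seq


@pytest.fixture(scope="module")
def locus():
    seq = random_seq(11, 800)
    amp = hand_amplicon("amp1", seq, 100, 120, 240, 260)
    design = hand_design(seq, [amp], 130, 230)
    return seq, amp, design


def read_from(seq_str, rid="r1", qual=40):
    return SimulatedRead(id=rid, seq=seq_str, quals=[qual] * len(seq_str))


class TestAssignRead:
    def test_exact_primer_prefix(self, locus):
        seq, amp, design = locus
        asn = assign_read(amp.fwd_primer_seq + seq[120:200], design)
        assert asn.amplicon_id == "amp1" and asn.strand == "+"

    def test_reverse_primer_prefix(self, locus):
        seq, amp, design = locus
        asn = assign_read(amp.rev_primer_seq + revcomp(seq[140:240]), design)
        assert asn.amplicon_id == "amp1" and asn.strand == "-"

    def test_mismatch_threshold_contract(self, locus):
        seq, amp, design = locus
        primer = list(amp.fwd_primer_seq)
        primer[3] = "A" if primer[3] != "A" else "C"
        one_mm = "".join(primer) + seq[120:200]
        assert assign_read(one_mm, design, max_mismatch=2).assigned
        for i in (5, 8, 11):
            primer[i] = "A" if primer[i] != "A" else "C"
        many_mm = "".join(primer) + seq[120:200]
        assert not assign_read(many_mm, design, max_mismatch=2).assigned

    def test_adapter_tail_prefix_is_skipped(self, locus):
        seq, amp, design = locus
        read = amp.fwd_tail + amp.fwd_primer_seq + seq[120:180]
        asn = assign_read(read, design)
        assert asn.assigned and asn.tail_offset == len(amp.fwd_tail)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_hamming_scan(self, mini_genome, data):
        reference, _, design = mini_genome
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        amp = design.amplicons[int(rng.integers(len(design.amplicons)))]
        n_mut = int(rng.integers(0, 4))
        base = amp.fwd_primer_seq + reference[amp.contig][amp.insert_start :][:80]
        read = list(base)
        for _ in range(n_mut):
            i = int(rng.integers(len(amp.fwd_primer_seq)))
            read[i] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        asn = assign_read(read, design, max_mismatch=2)

        def hamming(a, b):
            return sum(x != y for x, y in zip(a, b))

        brute = []
        for a in sorted(design.amplicons, key=lambda a: a.id):
            for primer, strand in ((a.fwd_primer_seq, "+"), (a.rev_primer_seq, "-")):
                mm = hamming(read[: len(primer)], primer)
                if mm <= 2 and len(read) >= len(primer):
                    brute.append((mm, a.id, strand))
        if not brute:
            assert not asn.assigned
        else:
            best = min(brute)
            assert (asn.mismatches, asn.amplicon_id) == (best[0], best[1])


class TestAlignInsert:
    def test_error_free_read_single_m_op(self, locus):
        seq, amp, design = locus
        read = read_from(seq[100:250])
        ar = align_insert(read, amp, {"chr1": seq})
        assert ar.ops == [("M", 150)]
        assert ar.aln_start == 100

    def test_adapter_readthrough_soft_clipped(self, locus):
        seq, amp, design = locus
        full = seq[100:260] + revcomp(simulate.REV_TAIL)
        read = read_from(full[:170])
        ar = align_insert(read, amp, {"chr1": seq})
        assert ar.ops == [("M", 160), ("S", 10)]

    @pytest.mark.parametrize("indel", ["insertion", "deletion"])
    def test_indel_matches_needleman_wunsch_oracle(self, locus, indel):
        seq, amp, design = locus
        if indel == "insertion":
            read_seq = seq[100:180] + "TTCA" + seq[180:260]
            expected_op = ("I", 4)
        else:
            read_seq = seq[100:180] + seq[184:260]
            expected_op = ("D", 4)
        ar = align_insert(read_from(read_seq), amp, {"chr1": seq})
        assert expected_op in ar.ops
        # independent oracle: Biopython global alignment, same affine scoring
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        span = seq[100:260]
        oracle_score = aligner.score(span, read_seq)
        # recompute my score from the op walk
        score = 0
        rp, qp = 0, 0
        for op, n in ar.ops:
            if op == "M":
                for k in range(n):
                    score += 2 if span[rp + k] == read_seq[qp + k] else -3
                rp += n
                qp += n
            elif op in "ID":
                score += -5 - (n - 1)
                if op == "I":
                    qp += n
                else:
                    rp += n
            else:
                qp += n
        assert score == oracle_score

    def test_insertion_left_aligned_in_repeat(self, locus):
        # duplication of a 4-mer inside a repeat must be reported left-most;
        # the repeat boundary is pinned so the placement is unambiguous
        seq, amp, _ = locus
        contig = seq[:149] + "TACACACACG" + seq[159:]
        amp2 = hand_amplicon("amp2", contig, 100, 120, 240, 260)
        # read duplicates one ACAC unit, synthesized mid-repeat
        read_seq = contig[100:154] + "ACAC" + contig[154:246]
        ar = align_insert(read_from(read_seq), amp2, {"chr1": contig})
        ins_ref_positions = [
            ref_pos for op, ref_pos, _rp, _n in ar.walk() if op == "I"
        ]
        assert ins_ref_positions == [150]  # left edge of the ACAC repeat

    def test_reverse_strand_read_aligns_to_same_span(self, locus):
        seq, amp, design = locus
        read_seq = amp.rev_primer_seq + revcomp(seq[110:240])
        ar = align_insert(read_from(read_seq), amp, {"chr1": seq}, strand="-")
        assert ar.strand == "-"
        assert ar.aln_end == 260
        assert ar.seq == revcomp(read_seq)

    def test_garbage_read_rejected(self, locus):
        seq, amp, design = locus
        from tilecall.align import AlignmentReject

        junk = read_from(random_seq(99, 150))
        assert isinstance(align_insert(junk, amp, {"chr1": seq}), AlignmentReject)


class TestTrimPrimers:
    def test_leading_primer_becomes_soft_clip(self, locus):
        seq, amp, design = locus
        ar = align_insert(read_from(seq[100:250]), amp, {"chr1": seq})
        trimmed = trim_primers(ar, amp)
        assert trimmed.ops[0] == ("S", 20)  # 20 bp fwd primer
        assert trimmed.aln_start == 120
        # trailing rev-primer bases 240..250 clipped too
        assert trimmed.ops == [("S", 20), ("M", 120), ("S", 10)]

    def test_idempotent(self, locus):
        seq, amp, design = locus
        ar = align_insert(read_from(seq[100:250]), amp, {"chr1": seq})
        once = trim_primers(ar, amp)
        twice = trim_primers(once, amp)
        assert twice.ops == once.ops and twice.aln_start == once.aln_start

    def test_conserves_read_length_and_sequence(self, locus):
        seq, amp, design = locus
        ar = align_insert(read_from(seq[100:250]), amp, {"chr1": seq})
        trimmed = trim_primers(ar, amp)
        assert trimmed.seq == ar.seq and trimmed.quals == ar.quals
        consumed = sum(n for op, n in trimmed.ops if op in "MIS")
        assert consumed == len(ar.seq)

    def test_no_aligned_op_left_in_primer_footprint(self, locus):
        seq, amp, design = locus
        ar = align_insert(read_from(seq[100:250]), amp, {"chr1": seq})
        trimmed = trim_primers(ar, amp)
        for op, ref_pos, _rp, n in trimmed.walk():
            if op in "MD":
                assert ref_pos >= amp.insert_start
                assert ref_pos + n <= amp.insert_end

    def test_read_entirely_in_primer_flagged_unusable(self, locus):
        seq, amp, design = locus
        ar = AlignedRead(
            read_id="x",
            amplicon_id=amp.id,
            contig="chr1",
            aln_start=100,
            ops=[("M", 15)],
            seq=seq[100:115],
            quals=[40] * 15,
        )
        assert trim_primers(ar, amp).unusable


class TestOnTarget:
    def test_rates(self, locus):
        seq, amp, design = locus
        good = read_from(amp.fwd_primer_seq + seq[120:200])
        bad = read_from(random_seq(42, 100))
        assert on_target_rate([assign_read(good.seq, design)]) == 1.0
        both = [assign_read(r.seq, design) for r in (good, bad)]
        assert on_target_rate(both) == 0.5

    def test_decoy_fraction_recovered(self, mini_genome):
        reference, _, design = mini_genome
        reads, origin = simulate.simulate_reads(
            design,
            reference,
            simulate.SampleTruth(),
            simulate.ErrorModel(mean_depth=30),
            seed=6,
            paired=False,
            decoy_fraction=0.1,
        )
        batch = align_reads(reads, design, reference)
        assert on_target_rate(batch.assignments) == pytest.approx(0.9, abs=0.02)
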