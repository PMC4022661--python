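"""Read assignment, primer-anchored insert alignment, and primer soft-clipping.

Amplicon reads need no genome-wide mapper: every read begins with the
synthesized primer of exactly one amplicon, so assignment is a Hamming scan
over the panel's primer prefixes and alignment is a banded, primer-anchored
semi-global dynamic program against that amplicon's reference span.  The key
downstream step is :func:`trim_primers`, which converts every read base whose
reference placement falls inside a primer footprint into a soft clip (``S``)
— removing synthesized primer bases from the pileup without touching the
read sequence — and reconstructs the alignment start accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .panel import Amplicon, PanelDesign, revcomp

__all__ = [
    "AlignedRead",
    "Assignment",
    "assign_read",
    "align_insert",
    "trim_primers",
    "on_target_rate",
]


@dataclass
class AlignedRead:
    """A read placed on the reference.

    ``ops`` is an ordered list of (op, length) with op in {M, I, D, S}; the
    read sequence is stored in reference orientation (reverse-strand reads
    are reverse-complemented before alignment, SAM-style).  Soft-clipped
    bases consume read but not reference.
    """

    read_id: str
    amplicon_id: str
    contig: str
    aln_start: int
    ops: list[tuple[str, int]]
    seq: str
    quals: list[int]
    strand: str = "+"
    unusable: bool = False

    def __post_init__(self) -> None:
        read_consumed = sum(n for op, n in self.ops if op in "MIS")
        if read_consumed != len(self.seq):
            raise ValueError(
                f"{self.read_id}: ops consume {read_consumed} read bases, "
                f"sequence has {len(self.seq)}"
            )

    @property
    def aln_end(self) -> int:
        return self.aln_start + sum(n for op, n in self.ops if op in "MD")

    def walk(self):
        """Yield (op, ref_pos, read_pos, length) for each op."""
        ref, read = self.aln_start, 0
        for op, n in self.ops:
            yield op, ref, read, n
            if op in "MS" or op == "I":
                read += n
            if op in "MD":
                ref += n


@dataclass
class Assignment:
    amplicon_id: str | None
    strand: str = "+"
    mismatches: int = 0
    tail_offset: int = 0

    @property
    def assigned(self) -> bool:
        return self.amplicon_id is not None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


class _PrimerIndex:
    """Exact-prefix lookup with Hamming-scan fallback over a panel's primers."""

    def __init__(self, design: PanelDesign):
        # candidates: (primer_as_synthesized, tail, amplicon_id, strand)
        self.candidates = []
        for a in sorted(design.amplicons, key=lambda a: a.id):
            self.candidates.append((a.fwd_primer_seq.upper(), a.fwd_tail, a.id, "+"))
            self.candidates.append((a.rev_primer_seq.upper(), a.rev_tail, a.id, "-"))
        self.exact: dict[str, tuple[str, str]] = {}
        for primer, _tail, amp_id, strand in reversed(self.candidates):
            self.exact[primer] = (amp_id, strand)
        self.lengths = sorted({len(p) for p, _, _, _ in self.candidates})


def build_primer_index(design: PanelDesign) -> _PrimerIndex:
    return _PrimerIndex(design)


def assign_read(
    read_seq: str,
    design: PanelDesign | _PrimerIndex,
    max_mismatch: int = 2,
    tail_max_mismatch: int = 2,
) -> Assignment:
    """Assign a read to the amplicon whose primer prefix it starts with.

    The expected primer may be preceded by the adapter tail (library
    read-through); a tail prefix matching within ``tail_max_mismatch`` is
    skipped before primer comparison.  The winner is the candidate with the
    fewest primer mismatches (<= ``max_mismatch``), ties broken by fewest
    mismatches then lexicographic amplicon id; no qualifying candidate means
    unassigned.
    """
    index = design if isinstance(design, _PrimerIndex) else _PrimerIndex(design)
    seq = read_seq.upper()
    # fast path: exact primer prefix
    for plen in index.lengths:
        hit = index.exact.get(seq[:plen])
        if hit is not None:
            return Assignment(amplicon_id=hit[0], strand=hit[1], mismatches=0)
    best: tuple[int, str, str, int] | None = None  # (mm, amp_id, strand, offset)
    for primer, tail, amp_id, strand in index.candidates:
        offsets = [0]
        if tail and _hamming(seq[: len(tail)], tail) <= tail_max_mismatch:
            offsets.append(len(tail))
        for off in offsets:
            window = seq[off : off + len(primer)]
            if len(window) < len(primer):
                continue
            mm = _hamming(window, primer)
            if mm <= max_mismatch:
                key = (mm, amp_id, strand, off)
                if best is None or key[:2] < best[:2]:
                    best = key
    if best is None:
        return Assignment(amplicon_id=None)
    return Assignment(
        amplicon_id=best[1], strand=best[2], mismatches=best[0], tail_offset=best[3]
    )


# ------------------------------------------------------------------ alignment

_MATCH, _MISMATCH = 2, -3
_GAP_OPEN, _GAP_EXT = -5, -1  # affine: opening gap base costs OPEN, each further EXT
_NEG = -(10**9)


def _banded_semiglobal(
    query: str, ref: str, band: int
) -> tuple[int, list[tuple[str, int]], int]:
    """Anchored-start banded Gotoh alignment of ``query`` against ``ref``.

    Global at the start (both begin at offset 0); free at the end on either
    side: trailing reference is ignored, trailing query bases become a soft
    clip.  Affine gap costs keep indels contiguous.  Returns
    (score, ops, n_trailing_clip).
    """
    n, m = len(query), len(ref)
    width = 2 * band + 1
    # layer 0 = M (diag), 1 = Ix (insertion, consumes query), 2 = Iy (deletion)
    dp = [[[_NEG] * width for _ in range(n + 1)] for _ in range(3)]
    tb = [[[0] * width for _ in range(n + 1)] for _ in range(3)]  # predecessor layer+1
    dp[0][0][band] = 0
    for k in range(band + 1, width):  # leading deletions
        j = k - band
        if j > m:
            break
        dp[2][0][k] = _GAP_OPEN + (j - 1) * _GAP_EXT
        tb[2][0][k] = 1 if j == 1 else 3
    for i in range(1, min(n, band) + 1):  # leading insertions
        dp[1][i][band - i] = _GAP_OPEN + (i - 1) * _GAP_EXT
        tb[1][i][band - i] = 1 if i == 1 else 2

    for i in range(1, n + 1):
        qi = query[i - 1]
        lo = max(1, i - band)
        hi = min(m, i + band)
        row_m, row_x, row_y = dp[0][i], dp[1][i], dp[2][i]
        prev_m, prev_x, prev_y = dp[0][i - 1], dp[1][i - 1], dp[2][i - 1]
        for j in range(lo, hi + 1):
            k = j - i + band
            # M: diagonal from any layer
            sub = _MATCH if qi == ref[j - 1] else _MISMATCH
            best, frm = _NEG, 0
            for layer, val in ((0, prev_m[k]), (1, prev_x[k]), (2, prev_y[k])):
                if val > best:
                    best, frm = val, layer
            if best > _NEG:
                row_m[k] = best + sub
                tb[0][i][k] = frm + 1
            # Ix: gap in reference (consume query), from cell (i-1, j)
            if k + 1 < width:
                open_s = prev_m[k + 1] + _GAP_OPEN
                ext_s = prev_x[k + 1] + _GAP_EXT
                if open_s >= ext_s and open_s > _NEG:
                    row_x[k] = open_s
                    tb[1][i][k] = 1
                elif ext_s > _NEG:
                    row_x[k] = ext_s
                    tb[1][i][k] = 2
            # Iy: gap in query (consume reference), from cell (i, j-1)
            if k - 1 >= 0:
                open_s = row_m[k - 1] + _GAP_OPEN
                ext_s = row_y[k - 1] + _GAP_EXT
                if open_s >= ext_s and open_s > _NEG:
                    row_y[k] = open_s
                    tb[2][i][k] = 1
                elif ext_s > _NEG:
                    row_y[k] = ext_s
                    tb[2][i][k] = 3

    best_score, best_state = _NEG, None
    i = n  # query consumed, trailing reference free
    for j in range(max(0, n - band), min(m, n + band) + 1):
        k = j - i + band
        for layer in (0, 1):
            if dp[layer][i][k] > best_score:
                best_score, best_state = dp[layer][i][k], (layer, i, j)
    for i in range(max(0, m - band), n):  # reference consumed, clip the rest
        j = m
        k = j - i + band
        if 0 <= k < width:
            for layer in (0, 1):
                if dp[layer][i][k] > best_score:
                    best_score, best_state = dp[layer][i][k], (layer, i, j)
    if best_state is None:
        return _NEG, [], 0

    layer, i, j = best_state
    clip = n - i
    rev_ops: list[str] = []
    while i > 0 or j > 0:
        k = j - i + band
        frm = tb[layer][i][k] - 1
        if layer == 0:
            rev_ops.append("M")
            i, j = i - 1, j - 1
        elif layer == 1:
            rev_ops.append("I")
            i -= 1
        else:
            rev_ops.append("D")
            j -= 1
        if frm < 0:  # pragma: no cover - anchored start always reachable
            break
        layer = frm
    ops: list[tuple[str, int]] = []
    for op in reversed(rev_ops):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return best_score, ops, clip


def _left_normalize(
    ops: list[tuple[str, int]], query: str, ref: str
) -> list[tuple[str, int]]:
    """Shift I/D runs to their left-most equivalent placement.

    An indel flanked on the left by sequence equal to its own trailing
    sequence can slide left without changing the alignment; VCF convention
    places it left-most.
    """
    # expand to per-base column list for simple manipulation
    cols: list[str] = []
    for op, n in ops:
        cols.extend(op * n)
    changed = True
    while changed:
        changed = False
        qpos = ref_pos = 0
        qoffs, roffs = [], []
        for c in cols:
            qoffs.append(qpos)
            roffs.append(ref_pos)
            if c in "MI":
                qpos += 1
            if c in "MD":
                ref_pos += 1
        i = 0
        while i < len(cols):
            if cols[i] in "ID":
                j = i
                while j < len(cols) and cols[j] == cols[i]:
                    j += 1
                # can the run [i, j) swap with a preceding M?
                if i > 0 and cols[i - 1] == "M":
                    if cols[i] == "I":
                        # last inserted base equals the M base before the run
                        if query[qoffs[j - 1]] == query[qoffs[i - 1]]:
                            cols[i - 1], cols[j - 1] = "I", "M"
                            changed = True
                            break
                    else:  # D
                        if ref[roffs[j - 1]] == ref[roffs[i - 1]]:
                            cols[i - 1], cols[j - 1] = "D", "M"
                            changed = True
                            break
                i = j
            else:
                i += 1
        if changed:
            continue
    out: list[tuple[str, int]] = []
    for c in cols:
        if out and out[-1][0] == c:
            out[-1] = (c, out[-1][1] + 1)
        else:
            out.append((c, 1))
    return out


@dataclass
class AlignmentReject:
    read_id: str
    reason: str


_FAST_PATH_MAX_MM = 4


def _ungapped_fast_path(
    seq: str,
    quals: list[int],
    span: str,
    strand: str,
    read_id: str,
    amplicon: Amplicon,
) -> AlignedRead | None:
    """Gap-free placement when the read matches the span within a few
    substitutions; an indel-carrying read fails the mismatch cap and falls
    through to the banded DP."""
    if strand == "-":
        seq_ro = revcomp(seq)
        quals = quals[::-1]
        n, m = len(seq_ro), len(span)
        aligned_len = min(n, m)
        clip = n - aligned_len  # read-through past the span's left edge
        window = seq_ro[clip:].upper()
        ref_window = span[m - aligned_len :].upper()
        if _hamming(window, ref_window) > _FAST_PATH_MAX_MM:
            return None
        ops: list[tuple[str, int]] = []
        if clip:
            ops.append(("S", clip))
        ops.append(("M", aligned_len))
        return AlignedRead(
            read_id=read_id,
            amplicon_id=amplicon.id,
            contig=amplicon.contig,
            aln_start=amplicon.outer_end - aligned_len,
            ops=ops,
            seq=seq_ro,
            quals=quals,
            strand="-",
        )
    n, m = len(seq), len(span)
    aligned_len = min(n, m)
    clip = n - aligned_len
    if _hamming(seq[:aligned_len].upper(), span[:aligned_len].upper()) > _FAST_PATH_MAX_MM:
        return None
    ops = [("M", aligned_len)]
    if clip:
        ops.append(("S", clip))
    return AlignedRead(
        read_id=read_id,
        amplicon_id=amplicon.id,
        contig=amplicon.contig,
        aln_start=amplicon.outer_start,
        ops=ops,
        seq=seq,
        quals=quals,
        strand="+",
    )


def align_insert(
    read,
    amplicon: Amplicon,
    reference: dict[str, str],
    band: int = 10,
    strand: str = "+",
    tail_offset: int = 0,
    min_score_per_base: float = 0.5,
) -> AlignedRead | AlignmentReject:
    """Primer-anchored banded alignment of a full read (untrimmed).

    The read — reverse-complemented first for reverse-strand assignments —
    is aligned globally-at-the-start against the amplicon's reference span
    ``[outer_start, outer_end)``; read bases running past the span (adapter
    read-through) become a trailing soft clip, and indels are left-aligned.
    Primer bases remain ``M`` ops here; :func:`trim_primers` clips them.
    Reads scoring below ``min_score_per_base`` per aligned base are rejected.
    """
    seq = read.seq[tail_offset:]
    quals = list(read.quals[tail_offset:])
    contig_seq = reference[amplicon.contig]
    span = contig_seq[amplicon.outer_start : amplicon.outer_end]

    fast = _ungapped_fast_path(seq, quals, span, strand, read.id, amplicon)
    if fast is not None:
        return fast

    if strand == "-":
        seq_ref_orient = revcomp(seq)
        quals = quals[::-1]
        # mirror so the anchored end (rev primer) is on the left
        q_m = seq_ref_orient[::-1]
        r_m = span[::-1]
        score, ops_m, clip = _banded_semiglobal(q_m.upper(), r_m.upper(), band)
        ops = list(reversed(ops_m))
        lead_clip, trail_clip = clip, 0
        seq_out = seq_ref_orient
    else:
        seq_out = seq
        score, ops, clip = _banded_semiglobal(seq.upper(), span.upper(), band)
        lead_clip, trail_clip = 0, clip

    aligned_len = sum(n for op, n in ops if op == "M")
    if not ops or aligned_len == 0 or score < min_score_per_base * aligned_len:
        return AlignmentReject(read_id=read.id, reason="low_alignment_score")

    q_aligned = seq_out[lead_clip : len(seq_out) - trail_clip]
    r_used = sum(n for op, n in ops if op in "MD")
    if strand == "-":
        ref_start = amplicon.outer_end - r_used
        ref_used = span[len(span) - r_used :]
    else:
        ref_start = amplicon.outer_start
        ref_used = span[:r_used]
    ops = _left_normalize(ops, q_aligned.upper(), ref_used.upper())

    full_ops: list[tuple[str, int]] = []
    if lead_clip:
        full_ops.append(("S", lead_clip))
    full_ops.extend(ops)
    if trail_clip:
        full_ops.append(("S", trail_clip))
    return AlignedRead(
        read_id=read.id,
        amplicon_id=amplicon.id,
        contig=amplicon.contig,
        aln_start=ref_start,
        ops=full_ops,
        seq=seq_out,
        quals=quals,
        strand=strand,
    )


# ------------------------------------------------------------------- trimming


def trim_primers(aligned: AlignedRead, amplicon: Amplicon) -> AlignedRead:
    """Soft-clip every read base whose reference placement lies in a primer
    footprint.

    ``M`` portions inside ``[insert_start, insert_end)`` survive; ``D`` ops
    are shrunk to the insert; insertions strictly inside a footprint are
    clipped, but insertions *at* a primer/insert boundary stay with the
    insert (they are sample-derived).  The read sequence and qualities are
    unchanged; ``aln_start`` advances past any newly clipped prefix.  A read
    left with no aligned base is flagged unusable.  Idempotent.
    """
    istart, iend = amplicon.insert_start, amplicon.insert_end
    lead_s = trail_s = 0
    mid: list[tuple[str, int]] = []

    def emit(op: str, n: int) -> None:
        nonlocal lead_s, trail_s
        if n <= 0:
            return
        if op == "S":
            if mid:
                trail_s += n
            else:
                lead_s += n
        else:
            mid.append((op, n))

    new_start: int | None = None
    for op, ref_pos, _read_pos, n in aligned.walk():
        if op == "S":
            emit("S", n)
        elif op == "M":
            left = max(0, min(n, istart - ref_pos))
            right = max(0, min(n, ref_pos + n - iend))
            keep = n - left - right
            emit("S", left)
            if keep > 0:
                if new_start is None:
                    new_start = max(ref_pos, istart)
                emit("M", keep)
            emit("S", right)
        elif op == "I":
            if istart <= ref_pos <= iend:  # boundary insertions stay
                if new_start is None and ref_pos == istart:
                    new_start = ref_pos
                emit("I", n)
            else:
                emit("S", n)
        elif op == "D":
            del_start, del_end = ref_pos, ref_pos + n
            keep_start = max(del_start, istart)
            keep_end = min(del_end, iend)
            if keep_end > keep_start and mid:
                # deletions consume no read bases; only meaningful between
                # retained aligned blocks
                mid.append(("D", keep_end - keep_start))

    # strip trailing D (a deletion at the block edge aligns nothing)
    while mid and mid[-1][0] == "D":
        mid.pop()
    while mid and mid[0][0] == "D":
        mid.pop(0)

    if not mid or all(op not in "MI" for op, _ in mid):
        return replace(
            aligned,
            ops=[("S", len(aligned.seq))],
            unusable=True,
            aln_start=aligned.aln_start,
        )

    merged: list[tuple[str, int]] = []
    if lead_s:
        merged.append(("S", lead_s))
    for op, n in mid:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if trail_s:
        if merged and merged[-1][0] == "S":
            merged[-1] = ("S", merged[-1][1] + trail_s)
        else:
            merged.append(("S", trail_s))
    assert new_start is not None
    return replace(aligned, ops=merged, aln_start=new_start)


def on_target_rate(assignments: list[Assignment]) -> float:
    """Fraction of reads assigned to some amplicon."""
    if not assignments:
        raise ValueError("no reads")
    return sum(a.assigned for a in assignments) / len(assignments)


@dataclass
class AlignmentBatch:
    """Aligned reads plus the rejects file content, for the on-target metric."""

    aligned: list[AlignedRead] = field(default_factory=list)
    rejects: list[AlignmentReject] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)


def align_reads(
    reads,
    design: PanelDesign,
    reference: dict[str, str],
    max_mismatch: int = 2,
    band: int = 10,
    trim: bool = True,
) -> AlignmentBatch:
    """Assign, align, and (optionally) primer-trim a batch of reads."""
    index = _PrimerIndex(design)
    amps = {a.id: a for a in design.amplicons}
    batch = AlignmentBatch()
    for read in reads:
        asn = assign_read(read.seq, index, max_mismatch=max_mismatch)
        batch.assignments.append(asn)
        if not asn.assigned:
            batch.rejects.append(AlignmentReject(read.id, "unassigned"))
            continue
        amp = amps[asn.amplicon_id]
        result = align_insert(
            read,
            amp,
            reference,
            band=band,
            strand=asn.strand,
            tail_offset=asn.tail_offset,
        )
        if isinstance(result, AlignmentReject):
            batch.rejects.append(result)
            continue
        if trim:
            result = trim_primers(result, amp)
            if result.unusable:
                batch.rejects.append(AlignmentReject(read.id, "fully_clipped"))
                continue
        batch.aligned.append(result)
    return batch
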