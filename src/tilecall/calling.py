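"""Quality-aware pileup over the reportable range and filtered variant calling.

The caller counts only non-soft-clipped bases with quality at or above the
floor (Q>=20 by default) and emits a variant when at least ``min_alt_reads``
(50 by default) reads support the alternate allele.  Sites with an allele
ratio below 0.2 are *not* discarded: they are routed to a review tier,
because true mosaic variants (and occasional true heterozygotes) present
with exactly that profile.  Bases at or below 50X coverage are flagged as
low-coverage intervals for orthogonal (Sanger) follow-up, and candidate
variants matching common population polymorphisms are filtered unless
explicitly protected.

Allele bookkeeping keeps per-column counts summing to depth: a read with an
insertion contributes a ``+SEQ`` allele *in place of* its anchor base; a
read with a deletion contributes ``-SEQ`` at the first deleted column and a
spanning placeholder ``*`` (never emitted) at subsequent deleted columns.
Indels are left-aligned by the aligner before they reach the pileup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignedRead
from .panel import ReportableRange

__all__ = [
    "FilterConfig",
    "PileupColumn",
    "CandidateVariant",
    "pileup",
    "call_variants",
    "flag_low_coverage",
    "filter_polymorphisms",
    "confirmation_worklist",
]


@dataclass
class FilterConfig:
    """Caller thresholds.

    ``min_base_qual`` is the per-base quality floor for counting;
    ``min_alt_reads`` the minimum variant-supporting read count for
    emission; ``low_cov_threshold`` the (inclusive) depth at or below which
    a base is flagged for Sanger fallback; ``low_ratio_cutoff`` the allele
    ratio below which an emitted variant enters the review tier.
    """

    min_base_qual: int = 20
    min_alt_reads: int = 50
    low_cov_threshold: int = 50
    low_ratio_cutoff: float = 0.2
    polymorphism_freq_cutoff: float = 0.01
    protected_variants: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.min_base_qual, self.min_alt_reads, self.low_cov_threshold) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.low_ratio_cutoff < 0 or self.polymorphism_freq_cutoff < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class PileupColumn:
    """Per-position allele tally restricted to counted bases."""

    contig: str
    pos: int  # 0-based
    ref: str
    allele_counts: dict[str, int] = field(default_factory=dict)
    qual_sums: dict[str, float] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    def mean_qual(self, allele: str) -> float | None:
        n = self.allele_counts.get(allele, 0)
        if n == 0 or allele not in self.qual_sums:
            return None
        return self.qual_sums[allele] / n


@dataclass
class CandidateVariant:
    contig: str
    pos1: int  # 1-based, VCF-style
    ref: str
    alt: str
    depth: int
    alt_count: int
    allele_ratio: float
    mean_alt_qual: float | None = None
    filters: set[str] = field(default_factory=set)
    risk_tier: str = "standard"  # standard | low_ratio_review
    protected: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.contig, self.pos1, self.ref, self.alt


def pileup(
    reads: Iterable[AlignedRead],
    reportable: ReportableRange,
    config: FilterConfig | None = None,
    reference: dict[str, str] | None = None,
) -> list[PileupColumn]:
    """One column per reportable base, from trimmed alignments.

    Soft-clipped bases never count; ``M`` bases below ``min_base_qual`` are
    excluded from both allele counts and depth.  A deletion is keyed (with
    its deleted reference sequence) at its first deleted column; an
    insertion replaces its anchor-base contribution with a ``+SEQ`` allele.
    """
    if config is None:
        config = FilterConfig()
    if reference is None:
        raise ValueError("pileup requires the reference to name ref alleles")
    columns: dict[tuple[str, int], PileupColumn] = {}
    for contig, pos in reportable.positions():
        columns[(contig, pos)] = PileupColumn(
            contig=contig, pos=pos, ref=reference[contig][pos].upper()
        )

    for ar in reads:
        if ar.unusable:
            continue
        seq = ar.seq.upper()
        for op, ref_pos, read_pos, n in ar.walk():
            if op == "M":
                for k in range(n):
                    q = ar.quals[read_pos + k]
                    if q < config.min_base_qual:
                        continue
                    col = columns.get((ar.contig, ref_pos + k))
                    if col is None:
                        continue
                    base = seq[read_pos + k]
                    col.allele_counts[base] = col.allele_counts.get(base, 0) + 1
                    col.qual_sums[base] = col.qual_sums.get(base, 0.0) + q
            elif op == "I":
                ins_seq = seq[read_pos : read_pos + n]
                anchor = ref_pos - 1
                col = columns.get((ar.contig, anchor))
                if col is None:
                    continue
                anchor_base = _anchor_base(ar, anchor, seq)
                if anchor_base is None:
                    continue
                base, q = anchor_base
                if q < config.min_base_qual:
                    continue
                # replace the anchor-base contribution with the insertion allele
                if col.allele_counts.get(base, 0) > 0:
                    col.allele_counts[base] -= 1
                    col.qual_sums[base] = col.qual_sums.get(base, 0.0) - q
                    if col.allele_counts[base] == 0:
                        del col.allele_counts[base]
                        col.qual_sums.pop(base, None)
                allele = f"+{ins_seq}"
                col.allele_counts[allele] = col.allele_counts.get(allele, 0) + 1
                col.qual_sums[allele] = col.qual_sums.get(allele, 0.0) + q
            elif op == "D":
                # a deletion carries no bases of its own: gate it on the
                # quality of the last read base consumed before the gap, so
                # deletion support is thinned by the quality filter at the
                # same rate as the surrounding depth
                anchor_q = ar.quals[read_pos - 1] if read_pos > 0 else 0
                if anchor_q < config.min_base_qual:
                    continue
                del_seq = (
                    reference[ar.contig][ref_pos : ref_pos + n].upper()
                    if reference
                    else "N" * n
                )
                first = columns.get((ar.contig, ref_pos))
                if first is not None:
                    allele = f"-{del_seq}"
                    first.allele_counts[allele] = first.allele_counts.get(allele, 0) + 1
                for k in range(1, n):
                    col = columns.get((ar.contig, ref_pos + k))
                    if col is not None:
                        col.allele_counts["*"] = col.allele_counts.get("*", 0) + 1
    return [columns[key] for key in sorted(columns)]


def _anchor_base(
    ar: AlignedRead, anchor_ref_pos: int, seq: str
) -> tuple[str, int] | None:
    """Base and quality this read aligned at ``anchor_ref_pos`` (M ops only)."""
    for op, ref_pos, read_pos, n in ar.walk():
        if op == "M" and ref_pos <= anchor_ref_pos < ref_pos + n:
            k = anchor_ref_pos - ref_pos
            return seq[read_pos + k], ar.quals[read_pos + k]
    return None


def call_variants(
    columns: Sequence[PileupColumn],
    config: FilterConfig | None = None,
    reference: dict[str, str] | None = None,
) -> list[CandidateVariant]:
    """Emit non-reference alleles passing the allele-count filter.

    An alt allele needs ``min_alt_reads`` supporting reads unless its key
    matches ``protected_variants`` (known causative variants are emitted
    regardless, flagged ``protected``).  Variants with allele ratio below
    ``low_ratio_cutoff`` are tiered ``low_ratio_review`` — flagged for
    confirmation, never dropped.
    """
    if config is None:
        config = FilterConfig()
    protected = set(config.protected_variants)
    out: list[CandidateVariant] = []
    for col in columns:
        depth = col.depth
        if depth == 0:
            continue
        for allele, count in sorted(col.allele_counts.items()):
            if allele in (col.ref, "*"):
                continue
            contig, pos1, ref, alt = _vcf_form(col, allele, reference)
            is_protected = (contig, pos1, ref, alt) in protected
            if count < config.min_alt_reads and not is_protected:
                continue
            ratio = count / depth
            out.append(
                CandidateVariant(
                    contig=contig,
                    pos1=pos1,
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    alt_count=count,
                    allele_ratio=ratio,
                    mean_alt_qual=col.mean_qual(allele),
                    filters=set() if count >= config.min_alt_reads else {"LowAlleleCount"},
                    risk_tier=(
                        "low_ratio_review"
                        if ratio < config.low_ratio_cutoff
                        else "standard"
                    ),
                    protected=is_protected,
                )
            )
    return out


def _vcf_form(
    col: PileupColumn, allele: str, reference: dict[str, str] | None
) -> tuple[str, int, str, str]:
    """Anchored 1-based (contig, pos, ref, alt) for an allele key."""
    if allele.startswith("+"):  # insertion anchored at this column
        return col.contig, col.pos + 1, col.ref, col.ref + allele[1:]
    if allele.startswith("-"):  # deletion whose first deleted base is this column
        deleted = allele[1:]
        if reference is not None and col.pos > 0:
            anchor = reference[col.contig][col.pos - 1].upper()
        else:
            anchor = "N"
        return col.contig, col.pos, anchor + deleted, anchor
    return col.contig, col.pos + 1, col.ref, allele


def flag_low_coverage(
    columns: Sequence[PileupColumn], config: FilterConfig | None = None
) -> list[tuple[str, int, int]]:
    """Maximal merged intervals of reportable bases at or below the coverage
    floor (inclusive, per the "<=50X" rule), as 0-based half-open BED tuples."""
    if config is None:
        config = FilterConfig()
    intervals: list[tuple[str, int, int]] = []
    for col in sorted(columns, key=lambda c: (c.contig, c.pos)):
        if col.depth > config.low_cov_threshold:
            continue
        if (
            intervals
            and intervals[-1][0] == col.contig
            and intervals[-1][2] == col.pos
        ):
            c, s, _ = intervals[-1]
            intervals[-1] = (c, s, col.pos + 1)
        else:
            intervals.append((col.contig, col.pos, col.pos + 1))
    return intervals


def filter_polymorphisms(
    candidates: Sequence[CandidateVariant],
    freq_table: dict[tuple[str, int, str, str], float],
    config: FilterConfig | None = None,
) -> list[CandidateVariant]:
    """Mark common polymorphisms and return the reportable set.

    Candidates whose population frequency reaches the cutoff receive the
    ``CommonPolymorphism`` filter and drop from the report — unless
    protected, in which case they are retained (known causative variants
    are never filtered, even outside the reportable range).
    """
    if config is None:
        config = FilterConfig()
    reportable: list[CandidateVariant] = []
    for v in candidates:
        freq = freq_table.get(v.key, 0.0)
        if freq >= config.polymorphism_freq_cutoff and not v.protected:
            v.filters.add("CommonPolymorphism")
            continue
        reportable.append(v)
    return reportable


def confirmation_worklist(
    reportables: Sequence[CandidateVariant],
    low_cov_intervals: Sequence[tuple[str, int, int]],
) -> list[tuple]:
    """Orthogonal-confirmation worklist: every reportable variant plus every
    low-coverage interval, deduplicated, in stable (contig, pos) order."""
    records: set[tuple] = set()
    for v in reportables:
        records.add(("variant", v.contig, v.pos1, v.ref, v.alt))
    for contig, start, end in low_cov_intervals:
        records.add(("low_coverage", contig, start, end))
    return sorted(records, key=lambda r: (r[1], r[2], r[0]))
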