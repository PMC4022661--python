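"""Targeted-panel model: genes, exons, reportable range, and the tiled amplicon design.

The unit of target enrichment is the :class:`Amplicon` — a PCR product whose
forward and reverse primer footprints flank a sample-derived *insert*.
Amplicons are laid out in an overlapping ("tiled") fashion so that each target
base lies within the insert of more than one amplicon where geometry allows;
this redundancy is what protects the assay against allele drop-out when a
sample polymorphism falls under a primer binding site.

Coordinates are 0-based, half-open throughout this package; 1-based
coordinates appear only in VCF output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TargetExon",
    "ReportableRange",
    "Amplicon",
    "PanelDesign",
    "PanelValidationError",
    "build_reportable_range",
    "insert_coverage",
    "check_primer_variant_overlap",
    "design_stats",
    "merge_intervals",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


class PanelValidationError(ValueError):
    """Raised when a panel design violates a structural invariant."""


@dataclass(frozen=True)
class TargetExon:
    """One exon of a panel gene.

    ``start``/``end`` are 0-based half-open positions on ``contig``.
    ``coding`` distinguishes coding exons (which define the reportable range)
    from non-coding ones.
    """

    gene: str
    contig: str
    start: int
    end: int
    coding: bool = True
    index: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon {self.gene}:{self.index} has start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReportableRange:
    """Union of coding exons, each extended by ``flank`` bases on both sides.

    Variants are clinically reported only within these merged intervals.
    """

    intervals: tuple[tuple[str, int, int], ...]
    flank: int = 5

    @property
    def width(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def __contains__(self, site: tuple[str, int]) -> bool:
        contig, pos = site
        return any(
            c == contig and start <= pos < end for c, start, end in self.intervals
        )

    def positions(self) -> Iterable[tuple[str, int]]:
        for contig, start, end in self.intervals:
            for pos in range(start, end):
                yield contig, pos


@dataclass(frozen=True)
class Amplicon:
    """A tiled PCR product: two primer footprints flanking an insert.

    ``outer_start``/``outer_end`` span both primers on the reference.  The
    insert — the only portion that carries sample-derived sequence — is
    ``[outer_start + fwd_primer_len, outer_end - rev_primer_len)``.  Primer
    sequences are stored as synthesized: the forward primer equals the
    reference top strand at its footprint, the reverse primer is the reverse
    complement of the reference at its footprint.  Adapter tails are the
    constant 5' extensions used for secondary amplification.
    """

    id: str
    contig: str
    outer_start: int
    outer_end: int
    fwd_primer_len: int
    rev_primer_len: int
    fwd_primer_seq: str
    rev_primer_seq: str
    fwd_tail: str = ""
    rev_tail: str = ""

    def __post_init__(self) -> None:
        if self.insert_end <= self.insert_start:
            raise ValueError(f"amplicon {self.id}: empty insert span")
        if len(self.fwd_primer_seq) != self.fwd_primer_len:
            raise ValueError(f"amplicon {self.id}: fwd primer length mismatch")
        if len(self.rev_primer_seq) != self.rev_primer_len:
            raise ValueError(f"amplicon {self.id}: rev primer length mismatch")

    @property
    def length(self) -> int:
        return self.outer_end - self.outer_start

    @property
    def insert_start(self) -> int:
        return self.outer_start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        return self.outer_end - self.rev_primer_len

    def primer_footprints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Reference intervals of the forward and reverse primer footprints."""
        return (
            (self.outer_start, self.insert_start),
            (self.insert_end, self.outer_end),
        )

    def in_primer(self, pos: int) -> bool:
        (fs, fe), (rs, re_) = self.primer_footprints()
        return fs <= pos < fe or rs <= pos < re_


@dataclass
class PanelDesign:
    """The full panel: amplicons, target exons, and the reportable range."""

    amplicons: list[Amplicon]
    targets: list[TargetExon]
    reportable: ReportableRange
    length_bounds: tuple[int, int] = (110, 199)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            raise PanelValidationError("amplicon ids are not unique")

    def amplicon(self, amp_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amp_id:
                return a
        raise KeyError(amp_id)

    def validate(self, reference: dict[str, str] | None = None) -> None:
        """Check structural invariants; raise :class:`PanelValidationError`.

        Length-bound violations only warn (out-of-range amplicons are assumed
        to have been redesigned empirically rather than rejected outright).
        """
        lo, hi = self.length_bounds
        for a in self.amplicons:
            if not lo <= a.length <= hi:
                warnings.warn(
                    f"amplicon {a.id} length {a.length} outside design bounds "
                    f"[{lo}, {hi}]",
                    stacklevel=2,
                )
            if reference is not None:
                ref = reference[a.contig]
                fwd_ref = ref[a.outer_start : a.insert_start]
                rev_ref = ref[a.insert_end : a.outer_end]
                if a.fwd_primer_seq.upper() != fwd_ref.upper():
                    raise PanelValidationError(
                        f"amplicon {a.id}: forward primer does not match reference"
                    )
                if a.rev_primer_seq.upper() != revcomp(rev_ref).upper():
                    raise PanelValidationError(
                        f"amplicon {a.id}: reverse primer does not match reference"
                    )
        cov = insert_coverage(self)
        if cov.gaps:
            raise PanelValidationError(
                f"{len(cov.gaps)} reportable base(s) not covered by any insert; "
                f"first gap {cov.gaps[0]}"
            )


def build_reportable_range(
    exons: Sequence[TargetExon], flank: int = 5
) -> ReportableRange:
    """Merge the coding exons, each extended by ``flank`` bases on both sides.

    Non-coding exons are excluded.  Raises ``ValueError`` on an empty exon
    list or when no exon is coding.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not exons:
        raise ValueError("exon list is empty")
    coding = [e for e in exons if e.coding]
    if not coding:
        raise ValueError("no coding exons to build a reportable range from")
    raw = [(e.contig, max(0, e.start - flank), e.end + flank) for e in coding]
    return ReportableRange(intervals=tuple(merge_intervals(raw)), flank=flank)


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping or bookended (contig, start, end) intervals."""
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(intervals):
        if merged and merged[-1][0] == contig and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (contig, prev[1], max(prev[2], end))
        else:
            merged.append((contig, start, end))
    return merged


@dataclass
class CoverageMap:
    """Per-reportable-base insert redundancy.

    ``counts`` maps (contig, pos) -> number of amplicon inserts covering the
    base; ``gaps`` lists bases covered by none, ``single`` bases covered by
    exactly one insert (drop-out-prone: a polymorphism under that amplicon's
    primer would silence the site entirely).
    """

    counts: dict[tuple[str, int], int]
    gaps: list[tuple[str, int]] = field(default_factory=list)
    single: list[tuple[str, int]] = field(default_factory=list)

    def histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist


def insert_coverage(design: PanelDesign) -> CoverageMap:
    """Count, for every reportable base, the amplicon inserts covering it."""
    counts: dict[tuple[str, int], int] = {
        site: 0 for site in design.reportable.positions()
    }
    for a in design.amplicons:
        for pos in range(a.insert_start, a.insert_end):
            key = (a.contig, pos)
            if key in counts:
                counts[key] += 1
    cov = CoverageMap(counts=counts)
    for site, c in counts.items():
        if c == 0:
            cov.gaps.append(site)
        elif c == 1:
            cov.single.append(site)
    cov.gaps.sort()
    cov.single.sort()
    return cov


def check_primer_variant_overlap(
    design: PanelDesign, variant_positions: Sequence[tuple[str, int]]
) -> list[tuple[str, tuple[str, int]]]:
    """Report every (amplicon id, position) where a variant falls inside a
    primer footprint.

    Positions inside inserts only are not reported; such sites are read from
    sample DNA, whereas under-primer sites are overwritten by the synthesized
    primer sequence and risk allele drop-out.
    """
    collisions: list[tuple[str, tuple[str, int]]] = []
    for a in design.amplicons:
        for contig, pos in variant_positions:
            if contig == a.contig and a.in_primer(pos):
                collisions.append((a.id, (contig, pos)))
    return collisions


def design_stats(design: PanelDesign) -> dict:
    """Summary statistics of the amplicon layout.

    Lengths are measured outer_start -> outer_end (primers included).
    """
    lengths = [a.length for a in design.amplicons]
    stats: dict = {"n_amplicons": len(lengths)}
    if lengths:
        stats.update(
            min_length=min(lengths),
            max_length=max(lengths),
            mean_length=sum(lengths) / len(lengths),
        )
        stats["redundancy_histogram"] = insert_coverage(design).histogram()
    else:
        stats.update(min_length=None, max_length=None, mean_length=None)
        stats["redundancy_histogram"] = {}
    return stats
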