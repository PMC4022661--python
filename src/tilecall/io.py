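"""Readers and writers for the panel's interchange formats.

Targets travel as BED6 (name = ``gene|exon_index``, score = 1 for coding
exons, 0 otherwise), the amplicon design as a documented tab-separated file,
reads as FASTQ (Sanger Phred+33), alignments as SAM, probe tracks and truth
tables as TSV, and variants as VCF 4.2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import Amplicon, PanelDesign, ReportableRange, TargetExon, build_reportable_range

if TYPE_CHECKING:  # pragma: no cover
    from .align import AlignedRead

DESIGN_COLUMNS = [
    "id",
    "contig",
    "outer_start",
    "outer_end",
    "fwd_len",
    "rev_len",
    "fwd_seq",
    "rev_seq",
    "fwd_tail",
    "rev_tail",
]


# ---------------------------------------------------------------------- FASTA


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------------ BED


def write_targets_bed(targets: Iterable[TargetExon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in targets:
            fh.write(
                f"{e.contig}\t{e.start}\t{e.end}\t{e.gene}|{e.index}\t"
                f"{1 if e.coding else 0}\t+\n"
            )


def read_targets_bed(path: str | Path) -> list[TargetExon]:
    targets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, name, score, _strand = line.rstrip("\n").split("\t")[:6]
            gene, idx = name.rsplit("|", 1)
            targets.append(
                TargetExon(
                    gene=gene,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    coding=bool(int(score)),
                    index=int(idx),
                )
            )
    return targets


def write_intervals_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


# --------------------------------------------------------------------- design


def write_design(design: PanelDesign, path: str | Path) -> None:
    rows = [
        {
            "id": a.id,
            "contig": a.contig,
            "outer_start": a.outer_start,
            "outer_end": a.outer_end,
            "fwd_len": a.fwd_primer_len,
            "rev_len": a.rev_primer_len,
            "fwd_seq": a.fwd_primer_seq,
            "rev_seq": a.rev_primer_seq,
            "fwd_tail": a.fwd_tail,
            "rev_tail": a.rev_tail,
        }
        for a in design.amplicons
    ]
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_design(
    path: str | Path, targets: list[TargetExon], flank: int = 5
) -> PanelDesign:
    df = pd.read_csv(path, sep="\t", dtype={"fwd_tail": str, "rev_tail": str})
    df = df.fillna({"fwd_tail": "", "rev_tail": ""})
    amplicons = [
        Amplicon(
            id=str(r.id),
            contig=str(r.contig),
            outer_start=int(r.outer_start),
            outer_end=int(r.outer_end),
            fwd_primer_len=int(r.fwd_len),
            rev_primer_len=int(r.rev_len),
            fwd_primer_seq=str(r.fwd_seq),
            rev_primer_seq=str(r.rev_seq),
            fwd_tail=str(r.fwd_tail),
            rev_tail=str(r.rev_tail),
        )
        for r in df.itertuples()
    ]
    reportable = build_reportable_range(targets, flank=flank)
    return PanelDesign(amplicons=amplicons, targets=list(targets), reportable=reportable)


# ---------------------------------------------------------------------- FASTQ


def write_fastq(reads, path: str | Path) -> None:
    """Write simulated reads (objects with id/seq/quals) as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fastq(path: str | Path):
    from .simulate import SimulatedRead

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SimulatedRead(
                id=rec.id,
                seq=str(rec.seq),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


# ------------------------------------------------------------------------ SAM


def write_sam(
    aligned: "Iterable[AlignedRead]",
    reference: dict[str, str],
    path: str | Path,
) -> None:
    """Emit alignments as SAM with soft clips as standard ``S`` CIGAR ops."""
    import pysam

    contigs = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
        "PG": [{"ID": "tilecall", "PN": "tilecall"}],
    }
    op_codes = {"M": 0, "I": 1, "D": 2, "S": 4}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = ar.read_id
            seg.query_sequence = ar.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in ar.quals)
            )
            seg.reference_id = contigs.index(ar.contig)
            seg.reference_start = ar.aln_start
            seg.cigartuples = [(op_codes[op], length) for op, length in ar.ops]
            seg.mapping_quality = 60
            seg.flag = 16 if ar.strand == "-" else 0
            seg.set_tag("XA", ar.amplicon_id)
            out.write(seg)


def read_sam(path: str | Path) -> "list[AlignedRead]":
    import pysam

    from .align import AlignedRead

    op_names = {0: "M", 1: "I", 2: "D", 4: "S"}
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            out.append(
                AlignedRead(
                    read_id=seg.query_name,
                    amplicon_id=seg.get_tag("XA") if seg.has_tag("XA") else "",
                    contig=seg.reference_name,
                    aln_start=seg.reference_start,
                    ops=[(op_names[o], n) for o, n in seg.cigartuples],
                    seq=seg.query_sequence,
                    quals=list(seg.query_qualities),
                    strand="-" if seg.is_reverse else "+",
                )
            )
    return out


# ------------------------------------------------------------------------ VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tilecall
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth at site">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Variant-supporting read count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele ratio AC/DP">
##INFO=<ID=TIER,Number=1,Type=String,Description="Artifact-risk tier">
##INFO=<ID=PROTECTED,Number=0,Type=Flag,Description="Known causative variant protected from filtering">
##FILTER=<ID=LowAlleleCount,Description="Fewer than the minimum variant-supporting reads">
##FILTER=<ID=LowQual,Description="Mean alt base quality below floor">
##FILTER=<ID=OffReportable,Description="Outside the reportable range">
##FILTER=<ID=CommonPolymorphism,Description="Population frequency above cutoff">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(candidates, path: str | Path) -> None:
    """Write candidate variants (1-based positions) as a minimal VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for v in candidates:
            filt = ";".join(sorted(v.filters)) if v.filters else "PASS"
            info = (
                f"DP={v.depth};AC={v.alt_count};AF={v.allele_ratio:.4f};"
                f"TIER={v.risk_tier}"
            )
            if v.protected:
                info += ";PROTECTED"
            qual = f"{v.mean_alt_qual:.0f}" if v.mean_alt_qual is not None else "."
            fh.write(
                f"{v.contig}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t{qual}\t{filt}\t{info}\n"
            )


# ------------------------------------------------------------------- tabular


def write_probe_track(track, path: str | Path) -> None:
    track.frame().to_csv(path, sep="\t", index=False)


def read_probe_track(path: str | Path):
    from .cnv import ProbeTrack

    df = pd.read_csv(path, sep="\t")
    return ProbeTrack.from_frame(df)


def write_truth(truth, path: str | Path) -> None:
    rows = [dataclasses.asdict(v) for v in truth.variants]
    pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "zygosity", "fraction", "haplotype"],
    ).to_csv(path, sep="\t", index=False)
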