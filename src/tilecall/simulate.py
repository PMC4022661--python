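"""Synthetic inputs for the pipeline, with recorded ground truth.

This module emulates the physics of tiled-amplicon target enrichment that the
rest of the package exists to handle:

* a mini-genome of several genes with exon/intron structure;
* a redundant, tiled amplicon panel whose primers carry constant adapter
  tails;
* reads whose *primer bases always report the synthesized primer sequence*,
  never the sample allele — the mechanism that makes untrimmed pileups
  reference-biased and primer soft-clipping necessary;
* allele drop-out: a sample variant under a primer footprint removes that
  amplicon's yield for the carrying haplotype (complete loss by default);
* heterozygous, homozygous, and mosaic variants with binomial allele
  sampling, base-quality-dependent substitution errors, and log-normal
  per-amplicon depth variation;
* aCGH probe tracks (13 probes per exon by default, intronic probes every
  2.5 kb) with Gaussian noise around per-copy-state log2 levels.

All generators are deterministic for a fixed seed; a single global seed fans
out to per-stage child streams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (
    Amplicon,
    PanelDesign,
    TargetExon,
    build_reportable_range,
    revcomp,
)

__all__ = [
    "Variant",
    "CnvEvent",
    "SampleTruth",
    "ErrorModel",
    "SimulatedRead",
    "FWD_TAIL",
    "REV_TAIL",
    "make_reference",
    "make_design",
    "simulate_reads",
    "make_reads_for_amplicon",
    "simulate_acgh",
]

# Constant 5' adapter extensions on the forward / reverse primers.
FWD_TAIL = "CGCTCTTCCGATCTCTG"
REV_TAIL = "TGCTCTTCCGATCTGAC"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# log2-ratio levels per copy state.  The heterozygous-deletion level sits at
# -0.7 — between the calling band edge (-0.45) and the homozygous-loss bound
# (-1) — rather than at the theoretical -1.0, so classification never
# straddles a band boundary.
DEFAULT_TRUE_LOG2 = {
    "neutral": 0.0,
    "het_del": -0.7,
    "hom_del": -2.5,
    "gain": 0.45,
    "high_gain": 1.0,
}


@dataclass(frozen=True)
class Variant:
    """A truth variant in anchored VCF style (0-based ``pos``).

    SNV: ``ref`` and ``alt`` both length 1.  Deletion: ``ref`` = anchor base +
    deleted bases, ``alt`` = anchor base.  Insertion: ``ref`` = anchor base,
    ``alt`` = anchor base + inserted bases.  ``fraction`` is the expected
    alt-carrying fraction of molecules (0.5 het, 1.0 hom, in (0, 1] for
    mosaic); ``haplotype`` links het variants in cis.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    zygosity: str = "het"  # het | hom | mosaic
    fraction: float = 0.5
    haplotype: int = 1

    def __post_init__(self) -> None:
        if self.zygosity == "het" and self.fraction != 0.5:
            raise ValueError("het variants have fraction 0.5")
        if self.zygosity == "hom" and self.fraction != 1.0:
            raise ValueError("hom variants have fraction 1.0")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.contig, self.pos, self.ref, self.alt


@dataclass(frozen=True)
class CnvEvent:
    """A copy-number event over ``[start, end)`` with an optional explicit
    log2 level overriding the copy-state default."""

    contig: str
    start: int
    end: int
    copy_state: str  # het_del | hom_del | gain | high_gain
    log2: float | None = None


@dataclass
class SampleTruth:
    variants: list[Variant] = field(default_factory=list)
    cnvs: list[CnvEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(v.contig, v.pos) for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError("variant positions must be unique")


@dataclass
class ErrorModel:
    """Sequencing-noise model.

    Per-base qualities are drawn from a discrete distribution; the
    substitution probability of a base is its Phred error, ``10**(-q/10)``.
    Per-amplicon depth is log-normal around ``mean_depth`` with coefficient
    of variation ``depth_cv``.
    """

    qual_values: tuple[int, ...] = (37, 32, 24, 12)
    qual_probs: tuple[float, ...] = (0.80, 0.12, 0.05, 0.03)
    mean_depth: int = 500
    depth_cv: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.qual_probs) - 1.0) > 1e-9:
            raise ValueError("qual_probs must sum to 1")
        if self.mean_depth <= 0 or self.depth_cv < 0:
            raise ValueError("depth parameters must be positive")

    @staticmethod
    def noise_free() -> "ErrorModel":
        return ErrorModel(qual_values=(40,), qual_probs=(1.0,))


@dataclass
class SimulatedRead:
    id: str
    seq: str
    quals: list[int]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ------------------------------------------------------------------ reference


def make_reference(
    seed: int,
    n_genes: int = 6,
    exons_per_gene: int | Sequence[int] = 4,
    exon_len_range: tuple[int, int] = (80, 260),
    intron_len_range: tuple[int, int] = (300, 600),
) -> tuple[dict[str, str], list[TargetExon]]:
    """Random mini-genome: one contig per gene, exons separated by introns.

    Deterministic for fixed seed.  Exon coordinates are returned as
    :class:`TargetExon` records (all coding).
    """
    if isinstance(exons_per_gene, int):
        exon_counts = [exons_per_gene] * n_genes
    else:
        exon_counts = list(exons_per_gene)
        if len(exon_counts) != n_genes:
            raise ValueError("exons_per_gene length must equal n_genes")
    if min(exon_counts) < 1 or min(exon_len_range) < 1 or min(intron_len_range) < 1:
        raise ValueError("sizes must be positive")

    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    targets: list[TargetExon] = []
    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        contig = f"chr{g + 1}"
        pos = int(rng.integers(*_incl(intron_len_range)))
        pieces: list[str] = [_random_dna(rng, pos)]
        for e in range(exon_counts[g]):
            elen = int(rng.integers(*_incl(exon_len_range)))
            targets.append(
                TargetExon(
                    gene=gene, contig=contig, start=pos, end=pos + elen, index=e + 1
                )
            )
            pieces.append(_random_dna(rng, elen))
            pos += elen
            ilen = int(rng.integers(*_incl(intron_len_range)))
            pieces.append(_random_dna(rng, ilen))
            pos += ilen
        reference[contig] = "".join(pieces)
    return reference, targets


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


# --------------------------------------------------------------------- design


def make_design(
    reference: dict[str, str],
    targets: Sequence[TargetExon],
    tile_overlap: int = 55,
    amplicon_len_range: tuple[int, int] = (110, 199),
    primer_len_range: tuple[int, int] = (18, 24),
    seed: int = 0,
    design_flank: int = 50,
    report_flank: int = 5,
) -> PanelDesign:
    """Tile amplicons over every coding exon plus ``design_flank`` bases.

    Successive inserts advance by ``insert_len - tile_overlap``, so with
    ``tile_overlap`` above half the insert length interior target bases fall
    in at least two inserts — the redundancy that protects against allele
    drop-out.  Adapter tails are attached verbatim.  Raises on geometry that
    cannot cover an exon (names the exon).
    """
    rng = np.random.default_rng(seed)
    lo_amp, hi_amp = amplicon_len_range
    lo_pr, hi_pr = primer_len_range
    if lo_amp <= 2 * hi_pr:
        raise ValueError("amplicon_len_range must exceed twice the max primer length")

    amplicons: list[Amplicon] = []
    for exon in targets:
        if not exon.coding:
            continue
        contig_seq = reference[exon.contig]
        region_start = exon.start - design_flank
        region_end = exon.end + design_flank
        if region_start - hi_pr < 0 or region_end + hi_pr > len(contig_seq):
            raise ValueError(
                f"exon {exon.gene}|{exon.index}: tiling would leave the contig"
            )
        k = 0
        insert_start = region_start
        while True:
            amp_len = int(rng.integers(lo_amp, hi_amp + 1))
            p_f = int(rng.integers(lo_pr, hi_pr + 1))
            p_r = int(rng.integers(lo_pr, hi_pr + 1))
            insert_len = amp_len - p_f - p_r
            if insert_len <= tile_overlap:
                insert_len = tile_overlap + 1  # keep the tiling advancing
                amp_len = insert_len + p_f + p_r
            insert_end = insert_start + insert_len
            outer_start = insert_start - p_f
            outer_end = insert_end + p_r
            if outer_end > len(contig_seq):
                raise ValueError(
                    f"exon {exon.gene}|{exon.index}: amplicon runs off contig"
                )
            k += 1
            amplicons.append(
                Amplicon(
                    id=f"{exon.gene}_e{exon.index}_a{k}",
                    contig=exon.contig,
                    outer_start=outer_start,
                    outer_end=outer_end,
                    fwd_primer_len=p_f,
                    rev_primer_len=p_r,
                    fwd_primer_seq=contig_seq[outer_start : outer_start + p_f],
                    rev_primer_seq=revcomp(contig_seq[insert_end:outer_end]),
                    fwd_tail=FWD_TAIL,
                    rev_tail=REV_TAIL,
                )
            )
            if insert_end >= region_end:
                break
            insert_start += insert_len - tile_overlap
    reportable = build_reportable_range(targets, flank=report_flank)
    return PanelDesign(
        amplicons=amplicons,
        targets=list(targets),
        reportable=reportable,
        length_bounds=amplicon_len_range,
    )


# ---------------------------------------------------------------------- reads


def _apply_variants(
    insert: str, insert_start: int, insert_end: int, variants: list[Variant]
) -> str:
    """Splice anchored-VCF-style variants into the insert sequence.

    Only variants wholly inside ``[insert_start, insert_end)`` are applied;
    primer-footprint bases are synthesized and never carry sample alleles.
    """
    applicable = sorted(
        (
            v
            for v in variants
            if v.pos >= insert_start and v.pos + len(v.ref) <= insert_end
        ),
        key=lambda v: v.pos,
    )
    out: list[str] = []
    cursor = insert_start
    for v in applicable:
        out.append(insert[cursor - insert_start : v.pos - insert_start])
        out.append(v.alt)
        cursor = v.pos + len(v.ref)
    out.append(insert[cursor - insert_start :])
    return "".join(out)


def _overlaps_primer(v: Variant, amp: Amplicon) -> bool:
    s, e = v.ref_span
    for fs, fe in amp.primer_footprints():
        if s < fe and e > fs:
            return True
    return False


def make_reads_for_amplicon(
    amplicon: Amplicon,
    reference: dict[str, str],
    variants: list[Variant],
    n_reads: int,
    read_len: int = 150,
    qual: int = 40,
    strand: str = "+",
    id_prefix: str = "c",
) -> list[SimulatedRead]:
    """Error-free reads from one amplicon, all carrying ``variants``.

    A deterministic building block for constructed fixtures (e.g. exact
    allele-count geometries); :func:`simulate_reads` is the stochastic
    generator.
    """
    seq = reference[amplicon.contig]
    insert = seq[amplicon.insert_start : amplicon.insert_end]
    sample_insert = _apply_variants(
        insert, amplicon.insert_start, amplicon.insert_end, variants
    )
    product = amplicon.fwd_primer_seq + sample_insert + revcomp(amplicon.rev_primer_seq)
    if strand == "+":
        read_seq = (product + revcomp(amplicon.rev_tail))[:read_len]
    else:
        read_seq = (revcomp(amplicon.fwd_tail + product))[:read_len]
    return [
        SimulatedRead(
            id=f"{id_prefix}{i}", seq=read_seq, quals=[qual] * len(read_seq)
        )
        for i in range(n_reads)
    ]


def simulate_reads(
    design: PanelDesign,
    reference: dict[str, str],
    truth: SampleTruth,
    error_model: ErrorModel | None = None,
    read_len: int = 150,
    paired: bool = True,
    seed: int = 0,
    depth_override: dict[str, int] | None = None,
    allele_assignment: str = "binomial",
    dropout_factor: float = 0.0,
    decoy_fraction: float = 0.0,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate panel reads for one sample.

    Each amplicon yields a log-normal number of molecules (or the count in
    ``depth_override``); a molecule is assigned a haplotype, carries the
    truth variants of that haplotype (hom always; mosaic with probability
    ``fraction``), and is *dropped with probability 1 - dropout_factor* if any
    carried variant lies under this amplicon's primer footprints (allele
    drop-out).  Reads start with the primer sequence as synthesized — primer
    bases never report the sample allele — and run into the opposite adapter
    tail when ``read_len`` exceeds the product.  ``allele_assignment``
    "deterministic" alternates haplotypes and fixes mosaic carrier counts to
    ``round(fraction * n)`` for exact allele ratios; "binomial" samples them.

    Returns the reads and an origin table (read id, amplicon, strand,
    haplotype, carried variant keys).  Truth variants captured by no insert
    trigger a warning and are recorded with amplicon "uncapturable".
    """
    if error_model is None:
        error_model = ErrorModel()
    if allele_assignment not in ("binomial", "deterministic"):
        raise ValueError("allele_assignment must be 'binomial' or 'deterministic'")
    rng_depth, rng_hap, rng_err, rng_decoy = _spawn(seed, 4)

    # variants not inside any insert are uncapturable
    origin_rows: list[dict] = []
    for v in truth.variants:
        s, e = v.ref_span
        captured = any(
            a.contig == v.contig and s >= a.insert_start and e <= a.insert_end
            for a in design.amplicons
        )
        if not captured:
            warnings.warn(f"truth variant {v.key} is not capturable by any insert")
            origin_rows.append(
                {
                    "read_id": "",
                    "amplicon_id": "uncapturable",
                    "strand": ".",
                    "haplotype": -1,
                    "variants": _vkey(v),
                }
            )

    reads: list[SimulatedRead] = []
    serial = 0
    qv = np.array(error_model.qual_values)
    qp = np.array(error_model.qual_probs)
    sigma = float(np.sqrt(np.log1p(error_model.depth_cv**2)))

    for amp in design.amplicons:
        if depth_override and amp.id in depth_override:
            n_mol = int(depth_override[amp.id])
        else:
            scale = float(np.exp(rng_depth.normal(0.0, sigma) - sigma**2 / 2))
            n_mol = max(1, round(error_model.mean_depth * scale))
        amp_vars = [v for v in truth.variants if v.contig == amp.contig]
        het = [v for v in amp_vars if v.zygosity == "het"]
        hom = [v for v in amp_vars if v.zygosity == "hom"]
        mosaic = [v for v in amp_vars if v.zygosity == "mosaic"]
        if allele_assignment == "deterministic":
            mosaic_carriers = {v.key: round(v.fraction * n_mol) for v in mosaic}
        for i in range(n_mol):
            if allele_assignment == "deterministic":
                hap = i % 2
                carried = [v for v in het if v.haplotype == hap] + hom
                carried += [v for v in mosaic if i < mosaic_carriers[v.key]]
            else:
                hap = int(rng_hap.integers(2))
                carried = [v for v in het if v.haplotype == hap] + hom
                carried += [
                    v for v in mosaic if rng_hap.random() < v.fraction
                ]
            if any(_overlaps_primer(v, amp) for v in carried):
                if dropout_factor <= 0.0 or rng_hap.random() >= dropout_factor:
                    continue  # allele drop-out: molecule fails to amplify
            strand = "+" if (i % 2 == 0) else "-"
            mates = ("+", "-") if paired else (strand,)
            for mate_strand in mates:
                base = make_reads_for_amplicon(
                    amp, reference, carried, 1, read_len, 40, mate_strand, "x"
                )[0]
                serial += 1
                rid = f"r{serial:07d}" + (
                    f"/{1 if mate_strand == '+' else 2}" if paired else ""
                )
                seq, quals = _add_errors(base.seq, qv, qp, rng_err)
                reads.append(SimulatedRead(id=rid, seq=seq, quals=quals))
                origin_rows.append(
                    {
                        "read_id": rid,
                        "amplicon_id": amp.id,
                        "strand": mate_strand,
                        "haplotype": hap,
                        "variants": ";".join(_vkey(v) for v in carried),
                    }
                )

    if decoy_fraction > 0:
        n_decoy = round(decoy_fraction / (1 - decoy_fraction) * len(reads))
        for _ in range(n_decoy):
            serial += 1
            rid = f"r{serial:07d}"
            seq = _random_dna(rng_decoy, read_len)
            seq2, quals = _add_errors(seq, qv, qp, rng_err)
            reads.append(SimulatedRead(id=rid, seq=seq2, quals=quals))
            origin_rows.append(
                {
                    "read_id": rid,
                    "amplicon_id": "decoy",
                    "strand": ".",
                    "haplotype": -1,
                    "variants": "",
                }
            )

    origin = pd.DataFrame(
        origin_rows,
        columns=["read_id", "amplicon_id", "strand", "haplotype", "variants"],
    )
    return reads, origin


def _vkey(v: Variant) -> str:
    return f"{v.contig}:{v.pos}:{v.ref}>{v.alt}"


def _add_errors(
    seq: str, qual_values: np.ndarray, qual_probs: np.ndarray, rng: np.random.Generator
) -> tuple[str, list[int]]:
    n = len(seq)
    quals = rng.choice(qual_values, size=n, p=qual_probs)
    err_p = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(n) < err_p)[0]
    if hits.size:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        for i in hits:
            others = [b for b in _BASES if b != arr[i]]
            arr[i] = others[int(rng.integers(3))]
        seq = arr.tobytes().decode()
    return seq, [int(q) for q in quals]


# -------------------------------------------------------- constructed fixtures


def make_primer_shadow_fixture(scale: int = 1, seed: int = 7):
    """Two overlapping amplicons where a het 4-bp insertion sits under
    amplicon A's reverse-primer footprint and inside amplicon B's insert.

    A contributes ``300 * scale`` reverse-strand reads that cover the site
    only within A's primer (so their bases there are synthesized primer
    sequence, i.e. reference); B contributes ``100 * scale`` reads of which
    ``44 * scale`` carry the insertion — fixing the untrimmed pileup
    fraction at 44/400 = 11% and the trimmed fraction at 44/100 = 44%.  The
    anchor context is pinned so left-alignment cannot move the insertion
    out of A's footprint.

    Returns a dict with reference, design, reads, the truth variant, and
    its protected-variant key (1-based).
    """
    from .panel import PanelDesign, TargetExon, build_reportable_range

    rng = np.random.default_rng(seed)
    seq = _random_dna(rng, 1000)
    seq = seq[:399] + "GA" + seq[401:]  # anchor 'A' at 400, 'G' before it
    reference = {"chr1": seq}
    exon = TargetExon("GENE1", "chr1", 300, 450, index=1)

    def _amp(name: str, fs: int, istart: int, iend: int, re_: int) -> Amplicon:
        return Amplicon(
            id=name,
            contig="chr1",
            outer_start=fs,
            outer_end=re_,
            fwd_primer_len=istart - fs,
            rev_primer_len=re_ - iend,
            fwd_primer_seq=seq[fs:istart],
            rev_primer_seq=revcomp(seq[iend:re_]),
            fwd_tail=FWD_TAIL,
            rev_tail=REV_TAIL,
        )

    amp_a = _amp("ampA", 240, 260, 390, 410)  # rev primer [390, 410) holds the site
    amp_b = _amp("ampB", 320, 340, 440, 460)  # insert [340, 440) holds the site
    design = PanelDesign(
        [amp_a, amp_b], [exon], build_reportable_range([exon]), length_bounds=(110, 199)
    )
    site = 400
    variant = Variant("chr1", site, seq[site], seq[site] + "CTTC", "het")
    reads = (
        make_reads_for_amplicon(amp_a, reference, [], 300 * scale, 150, 40, "-", "a")
        + make_reads_for_amplicon(amp_b, reference, [], 56 * scale, 150, 40, "+", "bw")
        + make_reads_for_amplicon(
            amp_b, reference, [variant], 44 * scale, 150, 40, "+", "bv"
        )
    )
    return {
        "reference": reference,
        "design": design,
        "reads": reads,
        "variant": variant,
        "protected_key": ("chr1", site + 1, seq[site], seq[site] + "CTTC"),
        "site": site,
    }


# ----------------------------------------------------------------------- aCGH


def simulate_acgh(
    targets: Sequence[TargetExon],
    cnvs: Sequence[CnvEvent] = (),
    probes_per_exon: int | Sequence[int] = 13,
    intron_spacing_bp: int = 2500,
    contig_lengths: dict[str, int] | None = None,
    true_log2: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Simulate an exon-focused aCGH probe track.

    Each exon receives ``probes_per_exon`` evenly spaced probes (a scalar, or
    one count per target exon); intronic sequence is covered every
    ``intron_spacing_bp``.  A probe's log2 ratio is its covering copy-number
    event's level (``CnvEvent.log2`` if set, else the copy-state default)
    plus Gaussian noise.  Returns a :class:`~tilecall.cnv.ProbeTrack`.
    """
    from .cnv import ProbeTrack

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(probes_per_exon, int):
        ppe = [probes_per_exon] * len(targets)
    else:
        ppe = list(probes_per_exon)
        if len(ppe) != len(targets):
            raise ValueError("probes_per_exon must match the number of targets")
    if min(ppe, default=1) < 1:
        raise ValueError("probes_per_exon must be >= 1")
    levels = dict(DEFAULT_TRUE_LOG2)
    if true_log2:
        levels.update(true_log2)

    rng = np.random.default_rng(seed)
    contigs = sorted({e.contig for e in targets})
    if contig_lengths is None:
        contig_lengths = {
            c: max(e.end for e in targets if e.contig == c) + 10 * intron_spacing_bp
            for c in contigs
        }

    positions: list[tuple[str, int]] = []
    for exon, k in zip(targets, ppe):
        step = exon.length / k
        positions.extend(
            (exon.contig, exon.start + int((i + 0.5) * step)) for i in range(k)
        )
    for c in contigs:
        exonic = [(e.start, e.end) for e in targets if e.contig == c]
        for pos in range(intron_spacing_bp // 2, contig_lengths[c], intron_spacing_bp):
            if not any(s <= pos < e for s, e in exonic):
                positions.append((c, pos))
    positions.sort()

    def level_at(contig: str, pos: int) -> float:
        for ev in cnvs:
            if ev.contig == contig and ev.start <= pos < ev.end:
                return ev.log2 if ev.log2 is not None else levels[ev.copy_state]
        return levels["neutral"]

    log2 = np.array([level_at(c, p) for c, p in positions])
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=len(log2))
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(len(positions))],
            "contig": [c for c, _ in positions],
            "pos": [p for _, p in positions],
            "log2": log2,
        }
    )
    return ProbeTrack.from_frame(frame)
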