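import numpy as np
import pytest
from hypothesis import settings

from tilecall import calling, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from tilecall.align import align_reads
from tilecall.panel import (
    Amplicon,
    PanelDesign,
    TargetExon,
    build_reportable_range,
    revcomp,
)


@pytest.fixture(scope="session")
def mini_genome():
    """Two genes, two exons each, with a validated tiled design."""
    reference, targets = simulate.make_reference(1, n_genes=2, exons_per_gene=2)
    design = simulate.make_design(reference, targets, seed=1)
    design.validate(reference)
    return reference, targets, design


def hand_amplicon(name, seq, fs, istart, iend, re_, contig="chr1"):
    """Amplicon with explicit footprint coordinates on a raw sequence."""
    return Amplicon(
        id=name,
        contig=contig,
        outer_start=fs,
        outer_end=re_,
        fwd_primer_len=istart - fs,
        rev_primer_len=re_ - iend,
        fwd_primer_seq=seq[fs:istart],
        rev_primer_seq=revcomp(seq[iend:re_]),
        fwd_tail=simulate.FWD_TAIL,
        rev_tail=simulate.REV_TAIL,
    )


def hand_design(seq, amplicons, exon_start, exon_end, contig="chr1"):
    exon = TargetExon("GENE1", contig, exon_start, exon_end, index=1)
    return PanelDesign(
        amplicons, [exon], build_reportable_range([exon]), length_bounds=(110, 199)
    )


def random_seq(seed, n=1000):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def run_pipeline(reads, design, reference, config=None, trim=True):
    """align -> (trim) -> pileup -> call; returns (candidates, columns, batch)."""
    if config is None:
        config = calling.FilterConfig()
    batch = align_reads(reads, design, reference, trim=trim)
    columns = calling.pileup(batch.aligned, design.reportable, config, reference)
    candidates = calling.call_variants(columns, config, reference)
    return candidates, columns, batch


def mosaic_recovery_sweep(seed=123):
    """200 mosaic SNVs (fractions 0.05-0.45) at site depth >= 2,000 through
    the full trim/pileup/call pipeline; returns per-variant recovery info."""
    reference, targets = simulate.make_reference(
        31, n_genes=2, exons_per_gene=4, exon_len_range=(300, 300)
    )
    # non-overlapping tiling: the sweep measures caller recovery at a known
    # per-site depth, not tiling redundancy
    design = simulate.make_design(
        reference, targets, seed=31, tile_overlap=0, amplicon_len_range=(170, 199)
    )
    # candidate sites: inside an insert, outside every primer footprint (the
    # design rule that primers avoid known variant positions), spaced >= 8 bp
    # so reads carry realistic, isolated mismatch loads
    sites: list[tuple[str, int]] = []
    last: dict[str, int] = {}
    for e in targets:
        amps = [a for a in design.amplicons if a.contig == e.contig]
        for pos in range(e.start, e.end):
            in_insert = any(a.insert_start <= pos < a.insert_end for a in amps)
            in_primer = any(a.in_primer(pos) for a in amps)
            if in_insert and not in_primer and pos - last.get(e.contig, -99) >= 8:
                sites.append((e.contig, pos))
                last[e.contig] = pos
    assert len(sites) >= 200
    rng = np.random.default_rng(99)
    idx = sorted(rng.choice(len(sites), size=200, replace=False))
    fractions = np.linspace(0.05, 0.45, 200)
    variants = []
    for i, f in zip(idx, fractions):
        contig, pos = sites[i]
        rb = reference[contig][pos]
        variants.append(
            simulate.Variant(
                contig, int(pos), rb, "A" if rb != "A" else "G", "mosaic", float(f)
            )
        )
    truth = simulate.SampleTruth(variants=variants)
    err = simulate.ErrorModel(qual_values=(37,), qual_probs=(1.0,))
    reads, _ = simulate.simulate_reads(
        design, reference, truth, err, seed=seed, paired=False, read_len=200,
        depth_override={a.id: 2100 for a in design.amplicons},
    )
    cfg = calling.FilterConfig(min_alt_reads=30)  # 0.05 * 2100 = 105 >> 30
    candidates, _, _ = run_pipeline(reads, design, reference, cfg)
    by_key = {(c.contig, c.pos1, c.ref, c.alt): c for c in candidates}
    results = []
    for v, f in zip(variants, fractions):
        c = by_key.get((v.contig, v.pos + 1, v.ref, v.alt))
        results.append(
            {
                "fraction": float(f),
                "found": c is not None,
                "depth": c.depth if c else 0,
                "ratio": c.allele_ratio if c else None,
            }
        )
    return results


@pytest.fixture(scope="session")
def mosaic_sweep():
    return mosaic_recovery_sweep()
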