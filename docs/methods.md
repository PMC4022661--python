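# Methods

## Panel model

A panel is a set of target exons (BED6; 0-based half-open coordinates
internally, 1-based only in VCF output), a *reportable range* — the union of
coding exons each widened by a configurable flank (default 5 bp) — and a
tiled amplicon design.  Each amplicon stores its outer span, primer
footprint lengths, primer sequences *as synthesized* (the reverse primer is
the reverse complement of its reference footprint), and the constant adapter
tails (`CGCTCTTCCGATCTCTG` forward, `TGCTCTTCCGATCTGAC` reverse).  The
design validator checks primer/reference identity and that every reportable
base lies in at least one amplicon insert; amplicon lengths outside the
design bounds (110–199 bp default) warn rather than fail, since out-of-spec
targets are redesigned empirically rather than rejected.  Two flanks play
different roles and are deliberately separate parameters: the 5 bp
*reporting* flank defines where variants are reported, while the generator's
50 bp *design* flank defines how far tiling extends past each exon.

## Synthetic data

The generator is first-class, tested code; its defaults are the study
conditions for every downstream check.

**Reads.**  Each amplicon yields a log-normal number of molecules (mean
depth 500, CV 0.3 by default, or an explicit per-amplicon override).  A
molecule draws a haplotype; heterozygous truth variants belong to a
haplotype (linking variants in cis), homozygous variants to both, and
mosaic variants are carried with per-molecule probability equal to their
fraction.  Two physical facts drive everything downstream:

1. *Primer bases always report the synthesized primer sequence.*  Reads are
   built as `primer + sample-insert (+ reverse-complemented opposite
   adapter tail when the read runs past the product)`, so a variant under a
   primer footprint is invisible in that amplicon's reads — the mechanism
   that makes untrimmed pileups reference-biased.
2. *Allele drop-out.*  A molecule whose carried haplotype has a variant
   inside this amplicon's primer footprints fails to amplify with
   probability `1 − dropout_factor`; the default factor 0 models complete
   drop-out (the worst case, and the conservative one for testing tiling
   rescue).

Per-base qualities come from a discrete distribution (default 80% Q37,
12% Q32, 5% Q24, 3% Q12) and substitution errors occur at the Phred rate
`10^(−q/10)` of the drawn quality.  A `deterministic` allele-assignment mode
alternates haplotypes and fixes mosaic carrier counts at `round(f·n)` for
exact-arithmetic fixtures.  One global seed fans out to per-stage child
streams via `numpy.random.SeedSequence.spawn`; every generator is
bit-reproducible under a fixed seed.

**What the generator does not emulate:** PCR chimeras, polymerase indel
slippage, strand bias, duplicate molecules, GC-dependent depth, and
alignment ambiguity from repetitive genomes (contigs are i.i.d. random
DNA).  Passing tests therefore demonstrate the *pipeline arithmetic* —
trimming, counting, thresholding, segmentation — under controlled
enrichment physics, not robustness to every artifact of real libraries.

**aCGH tracks.**  Probes are laid down at 13 per exon (configurable per
exon) plus intronic probes every 2.5 kb; a probe's log2 ratio is its copy
state's level plus Gaussian noise.  Default levels: 0 neutral, **−0.7
heterozygous deletion**, −2.5 homozygous loss, +0.45 gain, +1.0 high gain.
The het-del level sits at −0.7 rather than the theoretical −1.0 so that
classification exercises the −0.45 band edge without straddling the −1
homozygous-loss boundary — consistent with an aberration filter that places
het deletions above −1.

## Read assignment and alignment

Assignment is an exhaustive Hamming scan of both primers of every amplicon
against the read prefix (exact-prefix hash fast path first), with an
optional adapter-tail prefix skipped when it matches within 2 mismatches;
the best candidate wins at ≤ 2 primer mismatches (ties: fewest mismatches,
then lexicographic amplicon id).  Unassigned and discarded reads are
written to a rejects table; the on-target rate is assigned/total.

Alignment is a primer-anchored banded Gotoh dynamic program (match +2,
mismatch −3, gap open −5, extend −1, band ±10) of the full read against the
amplicon's reference span: global at the anchored start, free at the end on
either axis, so trailing adapter read-through becomes a soft clip.  Reads
matching the span within 4 substitutions take a gap-free fast path.  Affine
gap costs are essential: under linear costs a split insertion ties a
contiguous one.  Indels are normalized to their left-most equivalent
placement (VCF convention) by run rotation after traceback.  Alignments
scoring under 0.5 per aligned base are rejected with a reason.

**Primer trimming** is footprint-based, not sequence-based: every read base
whose *reference placement* falls inside a primer footprint becomes a soft
clip, deletions are shrunk to the insert, and insertions exactly at a
primer/insert boundary stay with the insert (they are sample-derived).
Read sequence and qualities are untouched; the alignment start is
reconstructed.  The operation is idempotent, and afterwards no M/I/D op
overlaps a footprint — so pileup depth at a footprint position comes only
from *other* amplicons' inserts, which is the entire point.

## Pileup and variant filters

One column per reportable base.  Only non-soft-clipped `M` bases with
quality ≥ `min_base_qual` (default Q20) are counted.  The Q20 rule is
applied at the *base* level (the variant-level quality is reported as mean
alt base quality but not thresholded), which is the testable reading of a
quality floor coupled to an allele-count floor.  Depth conservation — per
column, allele counts sum to depth — is kept exact for indels by
convention: an insertion-carrying read contributes a `+SEQ` allele *in
place of* its anchor-base count; a deletion-carrying read contributes
`-SEQ` at the first deleted column and a non-emittable `*` placeholder at
subsequent deleted columns.  A deletion carries no bases of its own, so its
contribution is gated on the quality of the last read base before the gap;
gating support and depth at the same rate keeps the allele-ratio estimator
unbiased (an ungated deletion count against a quality-thinned depth
overstates the ratio by the thinning factor).

Emission requires ≥ `min_alt_reads` (default 50) supporting reads —
consistent with 50X being the depth at which orthogonal (Sanger) follow-up
takes over — except for *protected* variants (a configured list of known
causative alleles), which are always emitted and flagged.  An allele ratio
below 0.2 routes the call to a `low_ratio_review` tier rather than
discarding it: genuine mosaics (and occasional true heterozygotes) present
exactly that profile, so sub-0.2 calls are confirmation work, not noise.
Bases at depth ≤ 50 (inclusive) are merged into low-coverage BED intervals;
candidates at population frequency ≥ 1% (configurable; no published
clinical cutoff exists, so this is an explicit config default) are filtered
as common polymorphisms unless protected.  The confirmation worklist is the
deduplicated union of reportable variants and low-coverage intervals.

## Copy-number calling

1. **Centralization** shifts the track so the KDE mode of the log2
   distribution sits at zero; the mode tracks the copy-neutral majority
   even when ~10% of probes sit in events, where the mean would not.
   Requires ≥ 20 probes.
2. **Noise** is estimated as `median|Δ| / (√2·0.6745)` over successive
   probe differences (derivative MAD) — robust to the events themselves.
3. **Segmentation** recursively extracts the interval maximizing the scan
   statistic `|mean(I)|·√n(I)/σ`, keeping intervals with score ≥ 6.0 and
   recursing into the flanks, then merges adjacent same-sign intervals.
   This is a documented stand-in for proprietary segmentation engines: it
   preserves the threshold semantics (the 6.0 default is kept as the
   filter's interface) but no equivalence to any proprietary score is
   claimed.  On tracks of ≤ 200 probes it provably matches an exhaustive
   all-intervals scan (tested).
4. **Fuzzy zero** removes segments with `|mean| < z·σ·(a + b/√n)` (defaults
   z = 2, a = 0.25, b = 1): the `b/√n` term is ordinary averaging of
   independent noise; the constant `a` models residual long-range
   correlated noise that does not average away, so long shallow segments
   (e.g. 500 probes at −0.08) are pruned while short deep ones (13 probes
   at −0.7) are untouched.  The constants are unpublished in any reference
   pipeline; these defaults are explicit config choices.
5. **Aberration filter and classes:** segments need ≥ 4 probes and
   |mean| outside the (−0.45, 0.35) neutral band; mean > 0.6 is a
   high-level gain, (0.35, 0.6] a single-copy gain, [−1, −0.45] a
   heterozygous deletion, < −1 a homozygous loss.  Calls are annotated with
   the exons they overlap and their genomic width.

With the default generator conditions (13 probes/exon, het-del level −0.7,
noise σ 0.15) the pipeline recovers 100/100 simulated single-exon het
deletions with zero calls on 100 neutral replicates; the acceptance
criterion is ≥ 95/100 and 0.

## Performance metrics and outcomes

Sensitivity is TP/(TP+FN) over variant keys, as a percent.  Analytical
specificity uses the per-base reading — true calls are the correctly
wild-type interrogated positions — i.e. `(N − FP)/N` over N interrogated
bases, *truncated* (not rounded) to two decimals so that, e.g., 30 FP over
5,788,250 bases displays as 99.99 rather than 100.00.  A sample is
*positive* if any reportable variant is pathogenic in the lookup table,
*inconclusive* if none is pathogenic but at least one is a variant of
uncertain significance (a variant missing from the table is treated as VUS
with a warning — the conservative default), else *negative*.  Cohort rates
are reported to one decimal with per-gene counts over positive drivers.

## Problem sizes used by the acceptance script

All figures are recomputed at desk scale on one CPU: the specificity and
cohort-rate arithmetic use the printed inputs (250 × 23,153 bp with 30 FP;
172/228/2,600 of 3,000); the trimming geometry uses 400 constructed reads
(300:100 insert depths, 44 variant reads, the variant registered as a known
causative — hence protected — allele so the 44-read support is emitted at
desk-scale depth); the mosaic deletion uses 7,439 simulated reads at one
site (binomial carriage at 0.149); the CNV checks use ~212–215-probe tracks.
The mosaic recovery sweep (200 variants, fractions 0.05–0.45, site depth
≥ 2,000) runs on a 2-gene mini-genome with non-overlapping tiling — the
sweep measures caller recovery at a known per-site depth, not tiling
redundancy — with variant sites kept out of primer footprints (the assay's
own design rule) and spaced ≥ 8 bp so per-read mismatch loads stay
realistic.

## Known limitations

* The aligner is primer-anchored and banded (±10); indels longer than the
  band or reads lacking a recognizable primer prefix are rejected, not
  rescued by genome-wide seeding.
* Multi-nucleotide variants are emitted as adjacent SNVs; no haplotype
  phasing or genotype likelihood model is attempted (counts and ratios
  only).
* Under extreme variant density (several alternate alleles within a few
  bases of each other) an affine-gap aligner can legitimately prefer a
  gapped realignment of a heavily mismatched read; allele counts at such
  sites are approximate.  Real panels avoid this regime by design.
* The segmentation scan statistic assumes approximately independent
  Gaussian probe noise; correlated wave artifacts of real arrays are
  handled only through the fuzzy-zero heuristic.
* ACMG-style pathogenicity classification is a lookup table by design;
  HGVS nomenclature and clinical report rendering are out of scope.
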