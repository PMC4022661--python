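import numpy as np
import pytest

from tilecall import calling, simulate
from tilecall.align import align_reads
from tilecall.calling import (
    CandidateVariant,
    FilterConfig,
    call_variants,
    confirmation_worklist,
    filter_polymorphisms,
    flag_low_coverage,
    pileup,
)
from tilecall.panel import PanelDesign, TargetExon, build_reportable_range

from conftest import hand_amplicon, hand_design, random_seq, run_pipeline


@pytest.fixture(scope="module")
def locus():
    seq = random_seq(13, 900)
    amp = hand_amplicon("amp1", seq, 100, 120, 240, 260)
    design = hand_design(seq, [amp], 130, 230)
    return seq, amp, design


class TestPileup:
    def test_error_free_ref_reads(self, locus):
        seq, amp, design = locus
        reads = simulate.make_reads_for_amplicon(amp, {"chr1": seq}, [], 100, 150)
        _, cols, _ = run_pipeline(reads, design, {"chr1": seq})
        for col in cols:
            assert col.depth == 100
            assert col.allele_counts == {col.ref: 100}

    def test_primer_only_coverage_is_zero_after_trimming(self, locus):
        seq, _, design = locus
        # an amplicon whose rev primer covers reportable bases [220, 240)
        amp2 = hand_amplicon("amp2", seq, 80, 100, 220, 240)
        design2 = hand_design(seq, [amp2], 130, 230)
        reads = simulate.make_reads_for_amplicon(
            amp2, {"chr1": seq}, [], 50, 160, strand="-"
        )
        _, cols, _ = run_pipeline(reads, design2, {"chr1": seq})
        under_primer = [c for c in cols if 220 <= c.pos < 235]
        assert under_primer and all(c.depth == 0 for c in under_primer)

    def test_counts_equal_bruteforce_tally(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        pos = 180
        var = simulate.Variant("chr1", pos, seq[pos], "A" if seq[pos] != "A" else "G")
        reads = simulate.make_reads_for_amplicon(
            amp, ref, [var], 7, 150
        ) + simulate.make_reads_for_amplicon(amp, ref, [], 11, 150, strand="-")
        cfg = FilterConfig(min_base_qual=20)
        _, cols, batch = run_pipeline(reads, design, ref, cfg)
        # naive per-base tally over the aligned reads
        brute: dict[tuple[int, str], int] = {}
        for ar in batch.aligned:
            for op, rp, qp, n in ar.walk():
                if op != "M":
                    continue
                for k in range(n):
                    if ar.quals[qp + k] >= 20 and (("chr1", rp + k) in
                                                    dict.fromkeys(design.reportable.positions())):
                        key = (rp + k, ar.seq[qp + k].upper())
                        brute[key] = brute.get(key, 0) + 1
        for col in cols:
            for allele, count in col.allele_counts.items():
                if len(allele) == 1 and allele in "ACGT":
                    assert brute.get((col.pos, allele), 0) == count

    def test_low_quality_bases_excluded(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        reads = simulate.make_reads_for_amplicon(amp, ref, [], 10, 150, qual=10)
        _, cols, _ = run_pipeline(reads, design, ref, FilterConfig(min_base_qual=20))
        assert all(c.depth == 0 for c in cols)

    def test_depth_conservation(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        pos = 180
        ins = simulate.Variant("chr1", pos, seq[pos], seq[pos] + "TTCA")
        dpos = 200
        dele = simulate.Variant("chr1", dpos, seq[dpos : dpos + 3], seq[dpos])
        reads = (
            simulate.make_reads_for_amplicon(amp, ref, [ins], 5, 150)
            + simulate.make_reads_for_amplicon(amp, ref, [dele], 6, 150)
            + simulate.make_reads_for_amplicon(amp, ref, [], 9, 150)
        )
        _, cols, _ = run_pipeline(reads, design, ref)
        for col in cols:
            assert sum(col.allele_counts.values()) == col.depth


class TestCallVariants:
    def test_threshold_boundary_49_suppressed_50_emitted(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        pos = 180
        var = simulate.Variant("chr1", pos, seq[pos], "A" if seq[pos] != "A" else "G")

        def ratio_call(n_alt):
            reads = simulate.make_reads_for_amplicon(
                amp, ref, [var], n_alt, 150
            ) + simulate.make_reads_for_amplicon(amp, ref, [], 200 - n_alt, 150)
            cands, _, _ = run_pipeline(reads, design, ref)
            return [c for c in cands if c.pos1 == pos + 1]

        assert ratio_call(49) == []
        emitted = ratio_call(50)
        assert len(emitted) == 1 and emitted[0].alt_count == 50

    def test_protected_variant_emitted_below_threshold(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        pos = 180
        alt = "A" if seq[pos] != "A" else "G"
        var = simulate.Variant("chr1", pos, seq[pos], alt)
        reads = simulate.make_reads_for_amplicon(
            amp, ref, [var], 10, 150
        ) + simulate.make_reads_for_amplicon(amp, ref, [], 190, 150)
        cfg = FilterConfig(protected_variants=[("chr1", pos + 1, seq[pos], alt)])
        cands, _, _ = run_pipeline(reads, design, ref, cfg)
        hits = [c for c in cands if c.pos1 == pos + 1]
        assert len(hits) == 1 and hits[0].protected

    def test_low_ratio_routed_to_review_not_dropped(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        pos = 180
        alt = "A" if seq[pos] != "A" else "G"
        var = simulate.Variant("chr1", pos, seq[pos], alt)
        reads = simulate.make_reads_for_amplicon(
            amp, ref, [var], 60, 150
        ) + simulate.make_reads_for_amplicon(amp, ref, [], 340, 150)
        cands, _, _ = run_pipeline(reads, design, ref)
        hit = next(c for c in cands if c.pos1 == pos + 1)
        assert hit.allele_ratio == pytest.approx(0.15)
        assert hit.risk_tier == "low_ratio_review"

    def test_raising_min_alt_reads_never_adds_variants(self, locus):
        seq, amp, design = locus
        ref = {"chr1": seq}
        rng = np.random.default_rng(5)
        reads = []
        for i, pos in enumerate(range(140, 220, 10)):
            alt = "A" if seq[pos] != "A" else "G"
            var = simulate.Variant("chr1", pos, seq[pos], alt)
            n = int(rng.integers(30, 120))
            reads += simulate.make_reads_for_amplicon(
                amp, ref, [var], n, 150, id_prefix=f"v{i}_"
            )
        reads += simulate.make_reads_for_amplicon(amp, ref, [], 100, 150)
        _, cols, _ = run_pipeline(reads, design, ref)
        emitted_sets = []
        for thresh in (10, 50, 80, 120):
            cfg = FilterConfig(min_alt_reads=thresh)
            emitted_sets.append({c.key for c in call_variants(cols, cfg, ref)})
        for smaller, larger in zip(emitted_sets[1:], emitted_sets):
            assert smaller <= larger


class TestLowCoverage:
    def _columns(self, depths, contig="chr1", start=0):
        cols = []
        for i, d in enumerate(depths):
            col = calling.PileupColumn(contig, start + i, "A")
            if d:
                col.allele_counts = {"A": d}
            cols.append(col)
        return cols

    def test_uniform_high_coverage_empty(self):
        assert flag_low_coverage(self._columns([9000] * 40)) == []

    def test_boundary_inclusive_at_50(self):
        cols = self._columns([100, 50, 100])
        assert flag_low_coverage(cols) == [("chr1", 1, 2)]

    def test_sawtooth_matches_linear_scan(self):
        rng = np.random.default_rng(2)
        depths = [int(rng.integers(0, 120)) for _ in range(300)]
        got = flag_low_coverage(self._columns(depths))
        flagged = [i for i, d in enumerate(depths) if d <= 50]
        brute = []
        for i in flagged:
            if brute and brute[-1][1] == i:
                brute[-1] = (brute[-1][0], i + 1)
            else:
                brute.append((i, i + 1))
        assert got == [("chr1", s, e) for s, e in brute]


class TestPolymorphismsAndWorklist:
    def _cand(self, pos, alt="G", **kw):
        defaults = dict(
            contig="chr1", pos1=pos, ref="A", alt=alt, depth=100, alt_count=60,
            allele_ratio=0.6,
        )
        defaults.update(kw)
        return CandidateVariant(**defaults)

    def test_common_polymorphism_filtered(self):
        v = self._cand(10)
        out = filter_polymorphisms([v], {v.key: 0.30}, FilterConfig())
        assert out == [] and "CommonPolymorphism" in v.filters

    def test_protected_polymorphism_retained(self):
        v = self._cand(10, protected=True)
        out = filter_polymorphisms([v], {v.key: 0.30}, FilterConfig())
        assert out == [v]

    def test_report_set_equals_set_algebra(self):
        rng = np.random.default_rng(3)
        cands = [self._cand(int(p)) for p in rng.choice(1000, 30, replace=False)]
        freq = {c.key: float(rng.random() * 0.05) for c in cands}
        cfg = FilterConfig(polymorphism_freq_cutoff=0.01)
        out = filter_polymorphisms(cands, freq, cfg)
        expected = {c.key for c in cands if freq[c.key] < 0.01}
        assert {c.key for c in out} == expected

    def test_worklist_counts_and_dedup(self):
        v1, v2 = self._cand(10), self._cand(20)
        wl = confirmation_worklist([v1, v2], [("chr1", 5, 8)])
        assert len(wl) == 3
        assert confirmation_worklist([], []) == []
        wl_dup = confirmation_worklist([v1, v1], [("chr1", 5, 8), ("chr1", 5, 8)])
        assert len(wl_dup) == 2


class TestAlleleDropout:
    """Tiling redundancy rescues a variant in cis with an under-primer
    polymorphism; a non-tiled single-amplicon design loses it entirely."""

    @pytest.fixture(scope="class")
    def fixture(self):
        seq = random_seq(17, 900)
        ref = {"chr1": seq}
        amp_a = hand_amplicon("ampA", seq, 100, 120, 240, 260)
        amp_b = hand_amplicon("ampB", seq, 40, 60, 190, 210)
        v_pos, p_pos = 180, 110  # variant mid-insert; polymorphism in A's fwd primer
        variant = simulate.Variant(
            "chr1", v_pos, seq[v_pos], "A" if seq[v_pos] != "A" else "G", "het"
        )
        poly = simulate.Variant(
            "chr1", p_pos, seq[p_pos], "A" if seq[p_pos] != "A" else "G", "het"
        )
        return ref, amp_a, amp_b, variant, poly

    def _call(self, ref, amps, variant, poly, depths):
        exon = TargetExon("GENE1", "chr1", 120, 240, index=1)
        design = PanelDesign(amps, [exon], build_reportable_range([exon]))
        truth = simulate.SampleTruth(variants=[variant, poly])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # poly may be uncapturable by design
            reads, _ = simulate.simulate_reads(
                design,
                ref,
                truth,
                simulate.ErrorModel.noise_free(),
                seed=4,
                paired=False,
                depth_override=depths,
                allele_assignment="deterministic",
            )
        cands, _, _ = run_pipeline(reads, design, ref)
        return [c for c in cands if c.pos1 == variant.pos + 1]

    def test_single_amplicon_design_misses_variant(self, fixture):
        ref, amp_a, _, variant, poly = fixture
        calls = self._call(ref, [amp_a], variant, poly, {"ampA": 400})
        assert calls == []

    def test_tiled_design_recovers_variant(self, fixture):
        ref, amp_a, amp_b, variant, poly = fixture
        calls = self._call(
            ref, [amp_a, amp_b], variant, poly, {"ampA": 400, "ampB": 400}
        )
        assert len(calls) == 1
        assert calls[0].alt_count >= 50


class TestTrimmingNecessity:
    """Primer soft-clipping converts an artifact-like 11% signal into a
    clean 44% heterozygous call on the overlapping-amplicon geometry."""

    def test_untrimmed_review_tier_trimmed_standard(self):
        fx = simulate.make_primer_shadow_fixture(scale=2)  # 88 alt reads >= 50
        untrimmed, _, _ = run_pipeline(
            fx["reads"], fx["design"], fx["reference"], trim=False
        )
        trimmed, _, _ = run_pipeline(fx["reads"], fx["design"], fx["reference"])
        site_hits = lambda cands: [c for c in cands if c.pos1 == fx["site"] + 1]
        u, t = site_hits(untrimmed), site_hits(trimmed)
        assert len(u) == 1 and len(t) == 1
        assert u[0].allele_ratio == pytest.approx(0.11)
        assert u[0].risk_tier == "low_ratio_review"
        assert t[0].allele_ratio == pytest.approx(0.44)
        assert t[0].risk_tier == "standard"


class TestMosaicRecovery:
    def test_parameter_recovery_mae_below_one_percent(self, mosaic_sweep):
        """200 simulated mosaics (fractions 0.05-0.45, site depth >= 2,000):
        every one is recovered and the mean absolute error of the reported
        allele ratio stays under 0.01."""
        for r in mosaic_sweep:
            assert r["found"], f"mosaic at fraction {r['fraction']:.2f} missed"
            assert r["depth"] >= 2000
        mae = float(np.mean([abs(r["ratio"] - r["fraction"]) for r in mosaic_sweep]))
        assert mae < 0.01
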