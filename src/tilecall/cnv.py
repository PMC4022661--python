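"""Exon-resolution copy-number calling on aCGH log2-ratio probe tracks.

Pipeline: ``centralize`` shifts the track so the copy-neutral mode sits at
zero; ``segment`` finds aberrant probe runs by recursive interval splitting
on the scan statistic ``|mean(I)| * sqrt(n(I)) / sd`` with a score
threshold (6.0 by default); ``fuzzy_zero`` prunes long, low-amplitude
segments attributable to residual long-range noise; ``call_aberrations``
applies the aberration filter — at least 4 probes, |mean log2| outside the
(-0.45, 0.35) neutral band — and classifies calls (mean > 0.6 high copy
gain, < -1 homozygous loss); ``annotate_exons`` maps calls to the exons
they overlap.

The per-track noise level is estimated from the median absolute successive
probe difference (derivative MAD), which is robust to the copy-number
events themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import TargetExon

__all__ = [
    "ProbeTrack",
    "Segment",
    "AberrationCall",
    "AcghConfig",
    "estimate_noise_sd",
    "centralize",
    "segment",
    "fuzzy_zero",
    "call_aberrations",
    "annotate_exons",
    "run_cnv_pipeline",
]


@dataclass
class AcghConfig:
    """Aberration-calling thresholds.

    The neutral band is ``(het_del_thresh, gain_thresh)``; segments need
    ``min_probes`` probes and a score of at least ``seg_score_thresh`` on
    the scan statistic.  The fuzzy-zero pruning bound is
    ``fuzzy_zero_z * sd * (fuzzy_zero_a + fuzzy_zero_b / sqrt(n))`` — the
    ``b/sqrt(n)`` term is ordinary averaging of independent noise, the
    constant ``a`` models residual long-range correlated noise that does
    not average away over long intervals.
    """

    min_probes: int = 4
    gain_thresh: float = 0.35
    het_del_thresh: float = -0.45
    high_gain_thresh: float = 0.6
    hom_del_thresh: float = -1.0
    seg_score_thresh: float = 6.0
    fuzzy_zero_enabled: bool = True
    fuzzy_zero_z: float = 2.0
    fuzzy_zero_a: float = 0.25
    fuzzy_zero_b: float = 1.0
    centralize_min_probes: int = 20

    def __post_init__(self) -> None:
        if not (
            self.hom_del_thresh
            < self.het_del_thresh
            < 0
            < self.gain_thresh
            < self.high_gain_thresh
        ):
            raise ValueError("aberration thresholds are not properly ordered")


@dataclass
class ProbeTrack:
    """Ordered aCGH probes with log2 ratios and a noise estimate."""

    probe_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    log2: np.ndarray
    noise_sd: float | None = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeTrack":
        df = df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
        log2 = np.asarray(df["log2"], dtype=float)
        if not np.all(np.isfinite(log2)):
            raise ValueError("log2 ratios must be finite")
        return cls(
            probe_ids=list(df["probe_id"].astype(str)),
            contigs=np.asarray(df["contig"].astype(str)),
            positions=np.asarray(df["pos"], dtype=int),
            log2=log2,
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "contig": self.contigs,
                "pos": self.positions,
                "log2": self.log2,
            }
        )

    def __len__(self) -> int:
        return len(self.log2)


@dataclass
class Segment:
    """A contiguous probe run with deviating mean log2."""

    contig: str
    start_idx: int  # probe index range within the contig's probe order
    end_idx: int  # half-open
    n_probes: int
    mean_log2: float
    score: float
    start_pos: int = 0
    end_pos: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment needs at least one probe")


@dataclass
class AberrationCall:
    segment: Segment
    copy_class: str  # gain | high_gain | het_del | hom_del
    exons: list[str] = field(default_factory=list)
    width_bp: int = 0

    def label(self) -> str:
        kind = "dup" if self.copy_class in ("gain", "high_gain") else "del"
        exon_part = ",".join(self.exons) if self.exons else "intronic"
        return f"{exon_part} {kind}, ~{self.width_bp / 1000:.1f} kb"


def estimate_noise_sd(log2: np.ndarray) -> float:
    """Derivative-MAD noise estimate: ``median|diff| / (sqrt(2) * 0.6745)``.

    Successive-difference based, so large but rare event-level shifts barely
    move it.
    """
    if len(log2) < 2:
        raise ValueError("need at least two probes to estimate noise")
    mad = float(np.median(np.abs(np.diff(log2))))
    sd = mad / (np.sqrt(2.0) * 0.6745)
    return max(sd, 1e-6)


def centralize(
    track: ProbeTrack, config: AcghConfig | None = None
) -> tuple[ProbeTrack, float]:
    """Shift the track so the mode of the log2 distribution sits at zero.

    The mode — estimated by Gaussian kernel density — tracks the copy-neutral
    probe mass even when a sizeable minority of probes sit in events, which
    the mean would not.  Returns (shifted track, applied shift).
    """
    if config is None:
        config = AcghConfig()
    if len(track) < config.centralize_min_probes:
        raise ValueError(
            f"centralization needs >= {config.centralize_min_probes} probes"
        )
    values = track.log2
    spread = float(values.max() - values.min())
    if spread < 1e-12:
        mode = float(values[0])
    else:
        kde = stats.gaussian_kde(values)
        grid = np.linspace(values.min(), values.max(), 2048)
        mode = float(grid[int(np.argmax(kde(grid)))])
    shifted = replace(track, log2=track.log2 - mode)
    shifted.noise_sd = estimate_noise_sd(shifted.log2)
    return shifted, -mode


def _best_interval(x: np.ndarray, sd: float) -> tuple[int, int, float]:
    """Highest-scoring subinterval under ``|sum| / sqrt(n) / sd``."""
    n = len(x)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    best_score, best_i, best_j = -1.0, 0, 1
    inv_sd = 1.0 / sd
    for i in range(n):
        lens = np.arange(1, n - i + 1)
        sums = prefix[i + 1 :] - prefix[i]
        scores = np.abs(sums) / np.sqrt(lens) * inv_sd
        k = int(np.argmax(scores))
        if scores[k] > best_score:
            best_score, best_i, best_j = float(scores[k]), i, i + k + 1
    return best_i, best_j, best_score


def segment(track: ProbeTrack, config: AcghConfig | None = None) -> list[Segment]:
    """Recursive interval splitting on the scan statistic.

    Within each contig the highest-scoring interval is accepted when its
    score reaches ``seg_score_thresh``; the search recurses into the flanks.
    Adjacent accepted intervals of the same sign are merged.  Probes outside
    every returned segment form the neutral baseline.
    """
    if config is None:
        config = AcghConfig()
    sd = track.noise_sd if track.noise_sd is not None else estimate_noise_sd(track.log2)

    segments: list[Segment] = []
    for contig in np.unique(track.contigs):
        mask = track.contigs == contig
        x = track.log2[mask]
        pos = track.positions[mask]
        found: list[tuple[int, int]] = []

        def recurse(lo: int, hi: int) -> None:
            if hi - lo < 1:
                return
            i, j, score = _best_interval(x[lo:hi], sd)
            if score < config.seg_score_thresh:
                return
            found.append((lo + i, lo + j))
            recurse(lo, lo + i)
            recurse(lo + j, hi)

        recurse(0, len(x))
        found.sort()
        merged: list[tuple[int, int]] = []
        for s, e in found:
            if (
                merged
                and merged[-1][1] == s
                and np.sign(x[merged[-1][0] : merged[-1][1]].mean())
                == np.sign(x[s:e].mean())
            ):
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            mean = float(x[s:e].mean())
            segments.append(
                Segment(
                    contig=str(contig),
                    start_idx=s,
                    end_idx=e,
                    n_probes=e - s,
                    mean_log2=mean,
                    score=float(abs(x[s:e].sum()) / np.sqrt(e - s) / sd),
                    start_pos=int(pos[s]),
                    end_pos=int(pos[e - 1]) + 1,
                )
            )
    return segments


def fuzzy_zero(
    segments: Sequence[Segment],
    track: ProbeTrack,
    config: AcghConfig | None = None,
) -> list[Segment]:
    """Prune long, low-amplitude segments.

    A segment is removed when ``|mean_log2|`` falls below
    ``z * sd * (a + b / sqrt(n))``: over long intervals independent noise
    averages away (the ``b/sqrt(n)`` term) but correlated long-range noise
    does not (the constant ``a``), so a long interval needs a non-vanishing
    mean to be trusted.  Short, high-amplitude segments are unaffected.
    Disabled -> identity.
    """
    if config is None:
        config = AcghConfig()
    if not config.fuzzy_zero_enabled:
        return list(segments)
    sd = track.noise_sd if track.noise_sd is not None else estimate_noise_sd(track.log2)
    kept = []
    for seg in segments:
        bound = (
            config.fuzzy_zero_z
            * sd
            * (config.fuzzy_zero_a + config.fuzzy_zero_b / np.sqrt(seg.n_probes))
        )
        if abs(seg.mean_log2) >= bound:
            kept.append(seg)
    return kept


def call_aberrations(
    segments: Sequence[Segment], config: AcghConfig | None = None
) -> list[AberrationCall]:
    """Apply the aberration filter and classify surviving segments.

    Drops segments with fewer than ``min_probes`` probes or mean log2 inside
    the neutral band; classifies the rest: mean > 0.6 high_gain, in
    (0.35, 0.6] gain, in [-1, -0.45] het_del, below -1 hom_del (default
    thresholds).
    """
    if config is None:
        config = AcghConfig()
    calls: list[AberrationCall] = []
    for seg in segments:
        if seg.n_probes < config.min_probes:
            continue
        m = seg.mean_log2
        if config.het_del_thresh < m < config.gain_thresh:
            continue
        if m > config.high_gain_thresh:
            cls = "high_gain"
        elif m >= config.gain_thresh:
            cls = "gain"
        elif m < config.hom_del_thresh:
            cls = "hom_del"
        else:
            cls = "het_del"
        calls.append(
            AberrationCall(
                segment=seg,
                copy_class=cls,
                width_bp=seg.end_pos - seg.start_pos,
            )
        )
    return calls


def annotate_exons(
    calls: Sequence[AberrationCall], targets: Sequence[TargetExon]
) -> list[AberrationCall]:
    """Label each call with the exons its genomic span overlaps."""
    ordered = sorted(targets, key=lambda e: (e.contig, e.start))
    for call in calls:
        seg = call.segment
        call.exons = [
            f"{e.gene}:ex{e.index}"
            for e in ordered
            if e.contig == seg.contig and e.start < seg.end_pos and e.end > seg.start_pos
        ]
        call.width_bp = seg.end_pos - seg.start_pos
    return list(calls)


def run_cnv_pipeline(
    track: ProbeTrack,
    targets: Sequence[TargetExon],
    config: AcghConfig | None = None,
) -> list[AberrationCall]:
    """centralize -> segment -> fuzzy_zero -> call_aberrations -> annotate."""
    if config is None:
        config = AcghConfig()
    centered, _shift = centralize(track, config)
    segs = segment(centered, config)
    segs = fuzzy_zero(segs, centered, config)
    calls = call_aberrations(segs, config)
    return annotate_exons(calls, targets)
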