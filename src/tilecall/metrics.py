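"""Assay-performance metrics and per-sample outcome classification.

Sensitivity is TP/(TP+FN) over variant keys.  Analytical specificity uses
the per-base reading: with FP false-positive calls over N interrogated
bases, the true calls are the N - FP correctly wild-type positions, giving
(N - FP)/N — displayed as a percentage truncated (not rounded) to two
decimals, so e.g. 30 FP over 5,788,250 bases displays as 99.99.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "SampleOutcome",
    "PerformanceReport",
    "sensitivity",
    "specificity",
    "classify_sample",
    "cohort_summary",
]


@dataclass
class SampleOutcome:
    sample_id: str
    category: str  # positive | inconclusive | negative
    driver_gene: str | None = None


@dataclass
class PerformanceReport:
    sensitivity: float
    specificity: float
    interrogated_bases: int
    tp_count: int
    fn_count: int
    fp_count: int
    mean_depth_per_exon: dict[str, float] = field(default_factory=dict)


def sensitivity(truth: Iterable[Hashable], called: Iterable[Hashable]) -> float:
    """TP/(TP+FN) over variant keys, as a percentage."""
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("truth set is empty")
    called_set = set(called)
    tp = len(truth_set & called_set)
    return 100.0 * tp / len(truth_set)


def specificity(interrogated_bases: int, fp_count: int) -> float:
    """Per-base analytical specificity, percent, truncated to 2 decimals.

    True calls = correctly wild-type interrogated positions =
    interrogated_bases - fp_count.
    """
    if interrogated_bases <= 0:
        raise ValueError("interrogated_bases must be positive")
    if not 0 <= fp_count <= interrogated_bases:
        raise ValueError("fp_count must lie in [0, interrogated_bases]")
    pct = 100.0 * (interrogated_bases - fp_count) / interrogated_bases
    return math.floor(pct * 100) / 100


def classify_sample(
    sample_id: str,
    reportables: Sequence,
    pathogenicity_table: Mapping[Hashable, str],
) -> SampleOutcome:
    """Positive if any reportable variant is pathogenic; else inconclusive if
    any is a VUS; else negative.  A variant absent from the lookup table is
    treated as a VUS with a warning.  ``reportables`` may be variant keys or
    objects with ``key``/``contig`` attributes.
    """
    classes: list[tuple[str, str | None]] = []
    for v in reportables:
        key = getattr(v, "key", v)
        gene = getattr(v, "gene", None)
        cls = pathogenicity_table.get(key)
        if cls is None:
            warnings.warn(f"variant {key} missing from pathogenicity table; treating as VUS")
            cls = "VUS"
        classes.append((cls, gene))
    for cls, gene in classes:
        if cls == "pathogenic":
            return SampleOutcome(sample_id, "positive", driver_gene=gene)
    if any(cls == "VUS" for cls, _ in classes):
        return SampleOutcome(sample_id, "inconclusive")
    return SampleOutcome(sample_id, "negative")


def cohort_summary(outcomes: Sequence[SampleOutcome]) -> dict:
    """Outcome rates (percent, 1 decimal) and per-gene positive counts."""
    if not outcomes:
        raise ValueError("no outcomes")
    n = len(outcomes)
    counts = {"positive": 0, "inconclusive": 0, "negative": 0}
    per_gene: dict[str, int] = {}
    for o in outcomes:
        counts[o.category] += 1
        if o.category == "positive" and o.driver_gene:
            per_gene[o.driver_gene] = per_gene.get(o.driver_gene, 0) + 1
    rates = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return {
        "n": n,
        "counts": counts,
        "rates_percent": rates,
        "positives_per_gene": dict(sorted(per_gene.items())),
    }
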