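"""Group-consensus peak calling and loop filtering.

A *consensus* (or "consistent") peak is a genomic region called a peak in at
least a threshold fraction — 60% by default — of a group's samples.  Candidate
regions are the merged union of every sample's peaks; support for a candidate
is the number of distinct samples contributing at least one overlapping base.
The fraction test uses exact integer arithmetic (``support * denom >= num``)
so that e.g. 3/5 passes a 0.6 threshold without floating-point edge cases.

Chromatin loops are retained only when both anchors land on a consensus peak
and the loop has sufficient read support (>= 2 reads by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

from .intervals import GenomicInterval, Loop, Peak, find_overlapping, merge_intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusPeakSet:
    """Consensus regions for one sample group, with per-region sample support."""

    group_id: str
    n_samples: int
    regions: tuple[tuple[GenomicInterval, int], ...]

    def __post_init__(self) -> None:
        for iv, support in self.regions:
            if not (0 < support <= self.n_samples):
                raise ValueError(
                    f"support {support} outside (0, {self.n_samples}] for {iv}"
                )
        for (a, _), (b, _) in zip(self.regions, self.regions[1:]):
            if (a.chrom, a.start) > (b.chrom, b.start) or (
                a.chrom == b.chrom and b.start < a.end
            ):
                raise ValueError(f"regions not sorted/disjoint at {a} vs {b}")

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.regions]

    def __len__(self) -> int:
        return len(self.regions)


def top_peaks_by_score(peaks: list[Peak], n_top: int) -> list[Peak]:
    """Optional pre-filter: keep the ``n_top`` highest-scoring peaks.

    Peaks without a score sort last; ties break by coordinate for determinism.
    """
    ranked = sorted(
        peaks,
        key=lambda p: (
            -(p.score if p.score is not None else float("-inf")),
            p.interval.chrom,
            p.interval.start,
            p.interval.end,
        ),
    )
    return ranked[:n_top]


def build_consensus_peaks(
    peaks_by_sample: dict[str, list[Peak]],
    threshold_fraction: float = 0.6,
    group_id: str = "",
) -> ConsensusPeakSet:
    """Merge all samples' peaks and keep regions supported by enough samples.

    A merged candidate region's support is the number of distinct samples with
    >= 1 bp overlapping it; the region is kept iff
    ``support / n_samples >= threshold_fraction`` (exact rational comparison).
    """
    if not peaks_by_sample:
        raise ValueError("peaks_by_sample is empty: need at least one sample")
    if not (0 < threshold_fraction <= 1):
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")

    n_samples = len(peaks_by_sample)
    all_intervals = [
        p.interval for peaks in peaks_by_sample.values() for p in peaks
    ]
    candidates = merge_intervals(all_intervals)

    support = [0] * len(candidates)
    for sample_peaks in peaks_by_sample.values():
        hit: set[int] = set()
        for p in sample_peaks:
            hit.update(find_overlapping(p.interval, candidates))
        for i in hit:
            support[i] += 1

    threshold = Fraction(threshold_fraction).limit_denominator(10**6)
    kept = tuple(
        (iv, s)
        for iv, s in zip(candidates, support)
        if Fraction(s, n_samples) >= threshold
    )
    logger.info(
        "consensus[%s]: %d candidate regions, %d retained at >= %s of %d samples",
        group_id, len(candidates), len(kept), threshold, n_samples,
    )
    return ConsensusPeakSet(group_id=group_id, n_samples=n_samples, regions=kept)


def filter_loops(
    loops: list[Loop],
    consensus: ConsensusPeakSet,
    min_reads: int = 2,
    anchor_pad: int = 0,
) -> list[Loop]:
    """Keep loops with >= ``min_reads`` support and both anchors on consensus peaks.

    ``anchor_pad`` expands each anchor before the overlap test (0 by default:
    anchors must genuinely share a base with a consensus region).  Order of the
    surviving loops follows the input; the operation is idempotent.
    """
    if len(consensus) == 0:
        raise ValueError("consensus peak set is empty")
    regions = consensus.intervals
    kept = []
    n_low_support = n_off_consensus = 0
    for loop in loops:
        if loop.read_support < min_reads:
            n_low_support += 1
            continue
        a1 = loop.anchor1.padded(anchor_pad)
        a2 = loop.anchor2.padded(anchor_pad)
        if find_overlapping(a1, regions) and find_overlapping(a2, regions):
            kept.append(loop)
        else:
            n_off_consensus += 1
    logger.info(
        "filter_loops: kept %d of %d (%d below %d reads, %d off-consensus)",
        len(kept), len(loops), n_low_support, min_reads, n_off_consensus,
    )
    return kept
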