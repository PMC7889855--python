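"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Every overlap and merge
operation in the package goes through the two functions defined here, so the
half-open convention is enforced in exactly one place.

Overlap requires at least one shared base pair; intervals that merely touch
(``a.end == b.start``) do not overlap.  Strand is carried on genes but never
consulted by overlap logic — CTCF anchors, accessible-chromatin peaks and LD
blocks are strandless features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def padded(self, pad: int) -> "GenomicInterval":
        """Return the interval expanded by ``pad`` bp on each side (clipped at 0)."""
        if pad == 0:
            return self
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A per-sample peak call (CTCF ChIP or ATAC)."""

    interval: GenomicInterval
    sample_id: str
    score: Optional[float] = None


@dataclass(frozen=True)
class LDBlock:
    """A linkage-disequilibrium block around a disease-risk lead SNP."""

    interval: GenomicInterval
    lead_snp: str


@dataclass(frozen=True)
class Gene:
    """A gene with its span and transcription start site.

    For ``+`` strand genes the TSS is the span start; for ``-`` strand genes it
    is the last covered base (``end - 1``).
    """

    gene_id: str
    span: GenomicInterval
    strand: str
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        tss = self.span.start if self.strand == "+" else self.span.end - 1
        object.__setattr__(self, "tss", tss)

    def promoter(self, pad: int = 2000) -> GenomicInterval:
        """Promoter window ``[tss - pad, tss + pad)``, clipped at chromosome start."""
        return GenomicInterval(
            self.span.chrom, max(0, self.tss - pad), self.tss + pad
        )


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchor intervals plus sequencing read support.

    Anchors are stored in canonical order (sorted by (chrom, start, end)) so a
    loop compares equal regardless of the orientation it was read in.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    read_support: int
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.read_support < 0:
            raise ValueError("read_support must be >= 0")
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def merge_intervals(items: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the union of ``items``.

    Touching intervals (half-open adjacency) are NOT merged: ``[100,200)`` and
    ``[200,300)`` stay separate segments.
    """
    ordered = sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def find_overlapping(
    query: GenomicInterval, sorted_targets: Sequence[GenomicInterval]
) -> list[int]:
    """Indices of ``sorted_targets`` overlapping ``query``.

    Targets must be sorted by (chrom, start); they need not be disjoint.
    Linear scan with an early break — fine at the scales this package handles,
    and immune to the bookkeeping bugs of interval-tree reuse.
    """
    hits = []
    for i, t in enumerate(sorted_targets):
        if t.chrom != query.chrom:
            continue
        if t.start >= query.end:
            # sorted within chromosome: nothing further can overlap
            if t.chrom == query.chrom:
                break
            continue
        if overlaps(query, t):
            hits.append(i)
    return hits
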