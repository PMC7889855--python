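"""Putative causal elements and their target genes.

A retained feature whose interval lies in a disease-risk LD block is a
putative causal element; every gene whose expression model retained that
feature is a putative target.  Output rows mirror the published report
format: element coordinates, element name (the overlapped gene's id, or a
stable ``Peak_<k>`` index for intergenic elements), the LD block's lead SNP,
the target gene, and an optional differential-expression flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .intervals import Gene, GenomicInterval, LDBlock, overlaps
from .selection import FeatureSelectionResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CausalAssignment:
    element_interval: GenomicInterval
    element_name: str
    ld_lead_snp: str
    target_gene_id: str
    target_is_de: Optional[bool] = None


def name_element(
    element_interval: GenomicInterval,
    genes: Sequence[Gene],
    peak_catalog: Optional[Sequence[GenomicInterval]] = None,
) -> str:
    """Gene-style name when the element overlaps a gene span, else ``Peak_<k>``.

    ``k`` is the element's 0-based index in the sorted ``peak_catalog``
    (typically the full ATAC consensus list), making intergenic names stable
    across runs.  Overlapping several genes takes the leftmost (tie noted).
    """
    hits = sorted(
        (g for g in genes if overlaps(element_interval, g.span)),
        key=lambda g: (g.span.start, g.gene_id),
    )
    if hits:
        if len(hits) > 1:
            logger.info(
                "element %s overlaps %d genes; using leftmost %s",
                element_interval, len(hits), hits[0].gene_id,
            )
        return hits[0].gene_id
    if peak_catalog is not None:
        ordered = sorted(peak_catalog, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for k, iv in enumerate(ordered):
            if iv == element_interval:
                return f"Peak_{k}"
        for k, iv in enumerate(ordered):  # fall back to overlap
            if overlaps(iv, element_interval):
                return f"Peak_{k}"
    return f"Peak_at_{element_interval.chrom}_{element_interval.start}"


def assign_causal_elements(
    results: Iterable[FeatureSelectionResult],
    ld_blocks: Sequence[LDBlock],
    genes: Sequence[Gene] = (),
    peak_catalog: Optional[Sequence[GenomicInterval]] = None,
    strict_containment: bool = False,
) -> list[CausalAssignment]:
    """One row per retained-feature-in-LD-block x target gene.

    ``strict_containment`` requires the element to lie entirely inside the
    block; the default accepts any overlap, consistent with hub seeding.
    Rows are sorted by (chrom, start, target gene) and are invariant to the
    order of ``results`` and ``ld_blocks``.
    """
    rows = []
    for res in results:
        for fid in res.retained_features:
            iv = res.feature_intervals.get(fid)
            if iv is None:
                raise KeyError(
                    f"retained feature {fid!r} of {res.target_gene_id} has no interval"
                )
            for block in ld_blocks:
                inside = (
                    block.interval.chrom == iv.chrom
                    and block.interval.start <= iv.start
                    and iv.end <= block.interval.end
                    if strict_containment
                    else overlaps(iv, block.interval)
                )
                if inside:
                    rows.append(
                        CausalAssignment(
                            element_interval=iv,
                            element_name=name_element(iv, genes, peak_catalog),
                            ld_lead_snp=block.lead_snp,
                            target_gene_id=res.target_gene_id,
                        )
                    )
    rows.sort(
        key=lambda a: (
            a.element_interval.chrom,
            a.element_interval.start,
            a.element_interval.end,
            a.target_gene_id,
            a.ld_lead_snp,
        )
    )
    logger.info("assign_causal_elements: %d rows", len(rows))
    return rows


def flag_de_targets(
    assignments: Sequence[CausalAssignment],
    de_gene_ids: Optional[Iterable[str]] = None,
) -> list[CausalAssignment]:
    """Mark targets present in an externally supplied differential list.

    With no list the flags stay ``None`` (differential expression analysis is
    outside this package's remit).
    """
    if de_gene_ids is None:
        return list(assignments)
    de = set(de_gene_ids)
    return [replace(a, target_is_de=a.target_gene_id in de) for a in assignments]


def assignments_to_rows(assignments: Sequence[CausalAssignment]) -> list[tuple]:
    return [
        (
            a.element_interval.chrom,
            a.element_interval.start,
            a.element_interval.end,
            a.element_name,
            a.target_gene_id,
            a.ld_lead_snp,
            "" if a.target_is_de is None else int(a.target_is_de),
        )
        for a in assignments
    ]


ASSIGNMENT_HEADER = (
    "feature_chrom",
    "feature_start",
    "feature_stop",
    "feature_name",
    "target_gene",
    "ld_lead_snp",
    "is_de",
)
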