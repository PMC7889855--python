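"""Count normalization and per-gene design matrices.

Expression and accessibility counts are normalized to log2 counts-per-million
with a prior count, the standard library-size-corrected form::

    log_cpm = log2( (count + prior) / (library_size + 2 * prior) * 1e6 )

which is finite at zero counts and strictly monotone in the count.  A gene is
*expressed* when at least ``min_samples`` samples reach CPM >= ``min_cpm``
(defaults 5 and 1).

For each hub and each expressed member gene, :func:`build_design` assembles
the model's regression problem: the target gene's log-CPM across matched
samples as the response, and the log-CPM of every *other* hub gene plus the
log-accessibility of every hub ATAC peak as the candidate features —
``(T - 1) + P`` columns for a hub with T genes and P peaks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hubs import Hub
from .intervals import GenomicInterval, overlaps


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    def row(self, feature_id: str) -> np.ndarray:
        return self.counts[self.feature_ids.index(feature_id)]


@dataclass
class LogCpmMatrix:
    """Features x samples log2 counts-per-million (same axes as its source)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("log-CPM values must be finite")

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


@dataclass
class HubDesign:
    """Per-target-gene regression problem: response Y_i, features Y_t and A_p."""

    target_gene_id: str
    sample_ids: list[str]
    response: np.ndarray
    feature_ids: list[str]
    feature_matrix: np.ndarray  # samples x features
    feature_intervals: dict = field(default_factory=dict)  # feature_id -> GenomicInterval

    def __post_init__(self) -> None:
        if self.target_gene_id in self.feature_ids:
            raise ValueError("target gene leaked into its own feature set")
        n, p = self.feature_matrix.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError("feature matrix shape mismatch")
        if len(self.response) != n:
            raise ValueError("response length mismatch")


def cpm(m: CountMatrix) -> np.ndarray:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    if (m.library_sizes <= 0).any():
        raise ValueError("zero library size")
    return m.counts / m.library_sizes * 1e6


def log_cpm(m: CountMatrix, prior: float = 0.5) -> LogCpmMatrix:
    """Prior-protected log2 CPM (finite at zero counts, monotone in counts)."""
    if prior <= 0:
        raise ValueError("prior must be > 0")
    vals = np.log2((m.counts + prior) / (m.library_sizes + 2 * prior) * 1e6)
    return LogCpmMatrix(
        feature_ids=list(m.feature_ids), sample_ids=list(m.sample_ids), values=vals
    )


def expressed_filter(
    m: CountMatrix, min_cpm: float = 1.0, min_samples: int = 5
) -> list[str]:
    """Feature ids with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    qualifying = (cpm(m) >= min_cpm).sum(axis=1)
    return [f for f, q in zip(m.feature_ids, qualifying) if q >= min_samples]


_COORD_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_coord_id(feature_id: str) -> Optional[GenomicInterval]:
    """Parse a ``chrom:start-end`` feature id into an interval, else None."""
    m = _COORD_ID.match(feature_id)
    if not m:
        return None
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


def match_peak_features(
    member_peaks: Sequence[tuple[str, GenomicInterval]], atac: LogCpmMatrix
) -> list[tuple[str, str, GenomicInterval]]:
    """Map hub member peaks onto rows of the ATAC matrix by interval overlap.

    ATAC feature ids must encode their interval as ``chrom:start-end``.
    Returns (peak_id, matrix_feature_id, consensus interval) triples; a member
    peak overlapping several matrix features yields one triple per feature.
    """
    feature_ivs = []
    for fid in atac.feature_ids:
        iv = parse_coord_id(fid)
        if iv is None:
            raise ValueError(
                f"ATAC feature id {fid!r} is not coordinate-formatted (chrom:start-end)"
            )
        feature_ivs.append((fid, iv))
    out = []
    for peak_id, region in member_peaks:
        for fid, iv in feature_ivs:
            if overlaps(region, iv):
                out.append((peak_id, fid, region))
    return out


def build_design(
    hub: Hub,
    rna: LogCpmMatrix,
    atac: LogCpmMatrix,
    target_gene_id: str,
    expressed_gene_ids: Optional[Sequence[str]] = None,
) -> HubDesign:
    """Assemble the response and candidate-feature matrix for one hub gene.

    Features are the log-CPM rows of the other hub member genes (restricted to
    ``expressed_gene_ids`` when given) followed by the log-CPM rows of the hub
    member ATAC peaks; both transposed to samples x features.  RNA and ATAC
    matrices must carry an identical, identically-ordered matched sample set.
    """
    if rna.sample_ids != atac.sample_ids:
        raise ValueError(
            "RNA and ATAC matrices must share an identical matched sample set; "
            f"got {rna.sample_ids} vs {atac.sample_ids}"
        )
    member_ids = [g.gene_id for g in hub.member_genes]
    if target_gene_id not in member_ids:
        raise ValueError(f"target gene {target_gene_id!r} is not a member of {hub.hub_id}")

    usable = set(rna.feature_ids)
    if expressed_gene_ids is not None:
        usable &= set(expressed_gene_ids)
    if target_gene_id not in usable:
        raise ValueError(f"target gene {target_gene_id!r} absent from the RNA matrix / expressed set")

    rows = []
    ids = []
    intervals: dict[str, GenomicInterval] = {}
    for g in hub.member_genes:
        if g.gene_id == target_gene_id or g.gene_id not in usable:
            continue
        rows.append(rna.row(g.gene_id))
        ids.append(g.gene_id)
        intervals[g.gene_id] = g.span
    for peak_id, fid, region in match_peak_features(hub.member_peaks, atac):
        if peak_id in intervals:
            continue  # member peak split across matrix rows: first overlap wins
        rows.append(atac.row(fid))
        ids.append(peak_id)
        intervals[peak_id] = region

    if not rows:
        raise ValueError(
            f"no candidate features for {target_gene_id!r} in {hub.hub_id}"
        )
    return HubDesign(
        target_gene_id=target_gene_id,
        sample_ids=list(rna.sample_ids),
        response=rna.row(target_gene_id).astype(float),
        feature_ids=ids,
        feature_matrix=np.column_stack(rows).astype(float)
        if len(rows) > 1
        else np.asarray(rows[0], dtype=float).reshape(-1, 1),
        feature_intervals=intervals,
    )
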