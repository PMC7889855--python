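import numpy as np
import pytest

from reghub.expression import HubDesign
from reghub.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_design(X, y, target="target"):
    """Wrap arrays as a HubDesign with generic feature names f0..fp-1."""
    n, p = X.shape
    return HubDesign(
        target_gene_id=target,
        sample_ids=[f"s{i}" for i in range(n)],
        response=np.asarray(y, float),
        feature_ids=[f"f{j}" for j in range(p)],
        feature_matrix=np.asarray(X, float),
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1000, max_len=120):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def base_set(intervals):
    """Per-base oracle: the exact set of (chrom, position) covered bases."""
    covered = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            covered.add((iv.chrom, pos))
    return covered


def oracle_segment_count(intervals):
    """Segments of the union under half-open merge semantics.

    A segment starts at a covered position p when p-1 is uncovered, or when
    no single input interval covers both p-1 and p (touching intervals are
    not merged).
    """
    covered = base_set(intervals)
    spanned = set()
    for iv in intervals:
        for p in range(iv.start + 1, iv.end):
            spanned.add((iv.chrom, p))
    return sum(
        1
        for (chrom, p) in covered
        if (chrom, p - 1) not in covered or (chrom, p) not in spanned
    )
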