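"""Readers and writers for the plain-text formats the pipeline consumes.

Dialects:

* peaks / LD blocks — BED3+ (``chrom  start  end  [name  [score]]``)
* loops — 7-column BEDPE-like
  (``chrom1 start1 end1 chrom2 start2 end2 read_support``)
* genes — TSV with header ``gene_id chrom start end strand``
* count matrices — TSV, header row of sample ids, first column feature ids

All coordinates are validated at the parser boundary (0-based half-open);
malformed lines raise :class:`ParseError` carrying the 1-based line number.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .intervals import Gene, GenomicInterval, LDBlock, Loop, Peak

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_interval(path, lineno, chrom: str, start: str, end: str) -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer coordinates {start!r}, {end!r}")
    try:
        return GenomicInterval(chrom, s, e)
    except ValueError as exc:
        raise ParseError(path, lineno, str(exc))


def read_bed_peaks(path: PathLike, sample_id: str = "") -> list[Peak]:
    """Read a BED3+ peak file; column 5 (if present) becomes the score."""
    peaks = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(cols)}")
        iv = _parse_interval(path, lineno, cols[0], cols[1], cols[2])
        score = None
        if len(cols) >= 5 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {cols[4]!r}")
        peaks.append(Peak(iv, sample_id=sample_id, score=score))
    return peaks


def read_bed_ld_blocks(path: PathLike) -> list[LDBlock]:
    """Read LD blocks from BED4 (name column = lead-SNP label)."""
    blocks = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 4:
            raise ParseError(
                path, lineno, f"LD blocks need 4 columns (lead SNP), got {len(cols)}"
            )
        iv = _parse_interval(path, lineno, cols[0], cols[1], cols[2])
        blocks.append(LDBlock(iv, lead_snp=cols[3]))
    return blocks


def read_bedpe_loops(path: PathLike, group_id: str = "") -> list[Loop]:
    """Read 7-column BEDPE-like loops with integer read support."""
    loops = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 7:
            raise ParseError(path, lineno, f"expected >=7 columns, got {len(cols)}")
        a1 = _parse_interval(path, lineno, cols[0], cols[1], cols[2])
        a2 = _parse_interval(path, lineno, cols[3], cols[4], cols[5])
        try:
            support = int(cols[6])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer read support {cols[6]!r}")
        if support < 0:
            raise ParseError(path, lineno, f"negative read support {support}")
        loops.append(Loop(a1, a2, read_support=support, group_id=group_id))
    return loops


def read_gene_table(path: PathLike) -> list[Gene]:
    """Read a gene annotation TSV (gene_id, chrom, start, end, strand)."""
    genes = []
    seen: set[str] = set()
    for lineno, cols in _data_lines(path):
        if lineno == 1 and cols[0] == "gene_id":
            continue
        if len(cols) < 5:
            raise ParseError(path, lineno, f"expected 5 columns, got {len(cols)}")
        gene_id, chrom, start, end, strand = cols[:5]
        if gene_id in seen:
            raise ParseError(path, lineno, f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        iv = _parse_interval(path, lineno, chrom, start, end)
        try:
            genes.append(Gene(gene_id, iv, strand))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    return genes


def read_count_matrix(path: PathLike):
    """Read a features x samples count matrix TSV into a CountMatrix."""
    from .expression import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(path, 0, f"duplicate feature ids {dupes}")
    if df.columns.has_duplicates:
        raise ParseError(path, 0, "duplicate sample ids in header")
    values = df.to_numpy()
    if (values < 0).any():
        raise ParseError(path, 0, "negative counts")
    return CountMatrix(
        feature_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=values,
    )


def write_count_matrix(matrix, path: PathLike) -> None:
    df = pd.DataFrame(
        matrix.counts, index=matrix.feature_ids, columns=matrix.sample_ids
    )
    df.to_csv(path, sep="\t")


def write_bed_peaks(peaks: Iterable[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\n")


def write_bed_ld_blocks(blocks: Iterable[LDBlock], path: PathLike) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            iv = b.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.lead_snp}\n")


def write_bedpe_loops(loops: Iterable[Loop], path: PathLike) -> None:
    with open(path, "w") as fh:
        for lo in loops:
            a, b = lo.anchor1, lo.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{lo.read_support}\n"
            )


def write_gene_table(genes: Iterable[Gene], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.span
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{g.strand}\n")


def write_table(rows: Sequence[Sequence], path: PathLike, header: Sequence[str]) -> None:
    """Write a generic TSV with a header row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
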