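"""Reference genome and alignment I/O: coverage and covered-region discovery.

The coverage model counts, at single-base resolution, the alignments whose
aligned reference blocks cover a base. Bases under a deletion in a read do
not count toward that read's coverage. Secondary (0x100), duplicate (0x400)
and supplementary (0x800) alignments are skipped by default to avoid double
counting; this is configurable.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from .types import GenomicInterval

DEFAULT_SKIP_FLAGS = 0x100 | 0x400 | 0x800  # secondary, duplicate, supplementary


class ReferenceGenome:
    """Random-access FASTA reference with 1-based inclusive coordinates."""

    def __init__(self, fasta_path: str):
        if not os.path.exists(fasta_path):
            raise FileNotFoundError(fasta_path)
        self._fasta = Fasta(fasta_path, sequence_always_upper=True)
        self.path = fasta_path

    @property
    def chromosomes(self) -> List[str]:
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence of [start, end], 1-based inclusive."""
        self._check_chrom(chrom)
        if start < 1 or end < start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        return str(self._fasta[chrom][start - 1 : end])

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not found in {self.path}")


def load_reference(fasta_path: str) -> ReferenceGenome:
    """Open a FASTA reference, building the .fai index if needed."""
    return ReferenceGenome(fasta_path)


class AlignmentView:
    """A (possibly chromosome-restricted) view over a sorted, indexed BAM."""

    def __init__(self, bam_path: str, chromosomes: Optional[Sequence[str]] = None):
        self.path = bam_path
        self._bam = pysam.AlignmentFile(bam_path, "rb")
        if not self._bam.has_index():
            raise ValueError(f"BAM file {bam_path} must be coordinate-sorted and indexed")
        header_chroms = list(self._bam.references)
        if chromosomes is None:
            self.chromosomes = header_chroms
        else:
            missing = [c for c in chromosomes if c not in header_chroms]
            if len(missing) == len(list(chromosomes)):
                raise ValueError(
                    f"none of the requested chromosomes are in the BAM header: {missing}"
                )
            self.chromosomes = [c for c in chromosomes if c in header_chroms]

    def chrom_length(self, chrom: str) -> int:
        return self._bam.get_reference_length(chrom)

    def fetch(self, chrom: str, start: int, end: int) -> Iterator[pysam.AlignedSegment]:
        """Alignments overlapping [start, end] (1-based inclusive)."""
        if chrom not in self.chromosomes:
            return iter(())
        return self._bam.fetch(chrom, start - 1, end)

    def __iter__(self) -> Iterator[pysam.AlignedSegment]:
        for chrom in self.chromosomes:
            yield from self._bam.fetch(chrom)

    def close(self) -> None:
        self._bam.close()

    def __enter__(self) -> "AlignmentView":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_alignments(bam_path: str) -> AlignmentView:
    return AlignmentView(bam_path)


def restrict_chromosomes(bam: AlignmentView, chroms: Sequence[str]) -> AlignmentView:
    """Restrict an alignment view to a subset of chromosomes."""
    if not chroms:
        raise ValueError("chromosome list must be non-empty")
    return AlignmentView(bam.path, chromosomes=chroms)


def coverage_track(
    bam: AlignmentView,
    chrom: str,
    skip_flags: int = DEFAULT_SKIP_FLAGS,
) -> np.ndarray:
    """Per-base read depth over one chromosome (index 0 = position 1).

    Depth at a base is the number of kept alignments with an aligned (gapless)
    block covering it; deleted bases inside a read do not contribute.
    """
    length = bam.chrom_length(chrom)
    delta = np.zeros(length + 1, dtype=np.int64)
    for read in bam.fetch(chrom, 1, length):
        if read.is_unmapped or (read.flag & skip_flags):
            continue
        for block_start, block_end in read.get_blocks():  # 0-based half-open
            delta[block_start] += 1
            delta[block_end] -= 1
    return np.cumsum(delta[:-1])


def covered_regions(
    bam: AlignmentView,
    min_coverage: int,
    skip_flags: int = DEFAULT_SKIP_FLAGS,
) -> List[GenomicInterval]:
    """Maximal runs of contiguous bases with depth >= min_coverage.

    Returns non-overlapping intervals sorted by (chromosome, start), merging
    adjacent qualifying bases.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    intervals: List[GenomicInterval] = []
    for chrom in bam.chromosomes:
        depth = coverage_track(bam, chrom, skip_flags=skip_flags)
        mask = depth >= min_coverage
        if not mask.any():
            continue
        # run boundaries of the boolean mask
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            intervals.append(GenomicInterval(chrom, int(s) + 1, int(e)))
    return intervals


def export_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")
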