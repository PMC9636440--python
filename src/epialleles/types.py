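"""Core domain types shared across the package.

Coordinates are 1-based and inclusive throughout the public API (the native
SAM/FASTA convention); conversions to 0-based half-open happen only at I/O
boundaries (pysam calls, BED export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Allowed cytosine dinucleotide contexts.
CONTEXTS = ("CG", "CA", "CC", "CT")

#: Matrix cell codes.
UNMETHYLATED = 0
METHYLATED = 1
AMBIGUOUS = 2


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "*"):
            raise ValueError(f"strand must be one of +, -, *: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class CpXSite:
    """A cytosine in a CpX dinucleotide context on one strand.

    ``pos`` is the 1-based position of the C itself: on the plus strand the
    reference base at ``pos`` is C and the context's second letter follows at
    ``pos + 1``; on the minus strand the reference (plus) base at ``pos`` is G
    and the dinucleotide read 5'->3' on the minus strand occupies plus-strand
    positions ``pos, pos - 1``.
    """

    chrom: str
    pos: int
    strand: str
    context: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"site strand must be + or -: {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}: {self.context!r}")

    @property
    def dinucleotide_span(self) -> Tuple[int, int]:
        """Plus-strand span (1-based inclusive) of the full dinucleotide."""
        if self.strand == "+":
            return (self.pos, self.pos + 1)
        return (self.pos - 1, self.pos)


@dataclass(frozen=True)
class AnalysisWindow:
    """A genomic window with the ordered CpX sites profiled inside it.

    ``strand_mode`` is ``"stranded"`` (sites of one strand, reads of that
    strand only) or ``"merged"`` (CG only: the two strands of each symmetric
    CpG unit are pooled; ``sites`` then hold the plus-strand C position of
    each unit and ``interval.strand`` is ``"*"``).
    """

    interval: GenomicInterval
    context: str
    sites: Tuple[int, ...]
    strand_mode: str = "stranded"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}: {self.context!r}")
        if self.strand_mode not in ("stranded", "merged"):
            raise ValueError(f"strand_mode must be stranded or merged: {self.strand_mode!r}")
        if self.strand_mode == "merged" and self.context != "CG":
            raise ValueError("merged strand mode is only defined for the symmetric CG context")
        if self.strand_mode == "stranded" and self.interval.strand == "*":
            raise ValueError("stranded windows must carry a definite strand")
        if list(self.sites) != sorted(self.sites):
            raise ValueError("sites must be sorted ascending")
        for p in self.sites:
            if not self.interval.contains(p):
                raise ValueError(f"site {p} outside window {self.interval}")

    @property
    def id(self) -> str:
        s = self.interval.strand
        return f"{self.interval.chrom}_{self.interval.start}_{self.interval.end}_{s}"

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def required_span(self) -> Tuple[int, int]:
        """Plus-strand span a read must cover to be informative at all sites.

        Extends the window interval to include the full dinucleotide of every
        site (the second base of an edge site may fall 1 bp outside the
        interval under the fixed-length scheme).
        """
        lo, hi = self.interval.start, self.interval.end
        for pos in self.sites:
            for strand in self.site_strands(pos):
                site = CpXSite(self.interval.chrom, pos, strand, self.context)
                a, b = site.dinucleotide_span
                lo, hi = min(lo, a), max(hi, b)
        return lo, hi

    def site_strands(self, pos: int) -> Tuple[str, ...]:
        if self.strand_mode == "merged":
            return ("+",)  # unit keyed by the plus-strand C; minus pair handled in extraction
        return (self.interval.strand,)


@dataclass
class BinaryEpialleleMatrix:
    """Reads x sites matrix of methylation calls for one window and sample.

    Cells are 0 (unmethylated), 1 (methylated) or 2 (ambiguous: non-bisulfite
    base, deletion, or below the quality floor). Rows exist for every read
    that spans the window end-to-end and passed conversion QC; rows containing
    a 2 are kept here but excluded from the compressed epiallele table and
    from all summary statistics.
    """

    window: AnalysisWindow
    read_ids: List[str]
    cells: np.ndarray  # shape (n_reads, n_sites), dtype int8
    read_strands: List[str]
    conversion_efficiencies: List[float]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2 or self.cells.shape[1] != self.window.n_sites:
            raise ValueError(
                f"matrix shape {self.cells.shape} incompatible with "
                f"{self.window.n_sites} window sites"
            )

    @property
    def n_reads(self) -> int:
        return self.cells.shape[0]

    @property
    def n_sites(self) -> int:
        return self.cells.shape[1]

    def unambiguous_rows(self) -> np.ndarray:
        """Boolean mask of rows free of ambiguous (2) calls."""
        return ~(self.cells == AMBIGUOUS).any(axis=1)

    def to_table(self, sample_id: str = "") -> "EpialleleTable":
        """Compress unambiguous rows to epiallele-string counts."""
        counts: Dict[str, int] = {}
        for row in self.cells[self.unambiguous_rows()]:
            key = "".join(map(str, row))
            counts[key] = counts.get(key, 0) + 1
        strand = self.window.interval.strand if self.window.strand_mode == "stranded" else "*"
        return EpialleleTable(
            window_id=self.window.id,
            sample_id=sample_id,
            strand=strand,
            counts=counts,
            n_sites=self.window.n_sites,
        )


@dataclass
class EpialleleTable:
    """Compressed per-window epiallele counts for one sample (and strand)."""

    window_id: str
    sample_id: str
    strand: str
    counts: Dict[str, int]
    n_sites: int

    def __post_init__(self) -> None:
        for key, count in self.counts.items():
            if len(key) != self.n_sites or set(key) - {"0", "1"}:
                raise ValueError(f"malformed epiallele string {key!r} for n={self.n_sites}")
            if count < 1:
                raise ValueError(f"epiallele count must be >= 1, got {count} for {key!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


#: Closed set of reasons a window can be dropped from the analysis.
EXCLUSION_REASONS = (
    "no_spanning_reads",
    "all_reads_ambiguous",
    "insufficient_coverage_after_qc",
)


@dataclass(frozen=True)
class ExcludedRegionRecord:
    """A window excluded from the analysis, with the reason."""

    window_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"reason must be one of {EXCLUSION_REASONS}: {self.reason!r}")
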