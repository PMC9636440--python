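"""Per-window epiallele extraction from bisulfite alignments.

For every analysis window and sample the reads spanning the window end to
end are collected and compared with the reference at each CpX position.
Bisulfite chemistry converts unmethylated C to T (read as T on the
originating strand, hence as A on the plus representation of a minus-strand
read), so at a plus-strand site C means methylated and T unmethylated; at a
minus-strand site the plus-representation bases are G (methylated) and A
(unmethylated). Any other base — a polymorphism, sequencing error or a
deletion — yields the ambiguous code 2, and such reads are excluded from
the compressed epiallele table.

The strand a read originates from is taken from the Bismark ``XG`` tag
("CT" = original top / plus, "GA" = original bottom / minus) when present,
falling back to the reverse-strand FLAG bit. Bisulfite strand of origin is
not in general the mapping strand of every mate, so the tag is authoritative.

Per-read bisulfite conversion efficiency is the fraction of reference
cytosines on the read's strand inside the window, outside the CG context
(and outside the analyzed context when that differs from CG), that the read
shows as converted. Reads below a user threshold can optionally be removed
before the table is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .genomeio import DEFAULT_SKIP_FLAGS, AlignmentView, ReferenceGenome
from .regions import COMPLEMENT
from .types import (
    AMBIGUOUS,
    METHYLATED,
    UNMETHYLATED,
    AnalysisWindow,
    BinaryEpialleleMatrix,
    CpXSite,
    EpialleleTable,
    ExcludedRegionRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class ExtractionParams:
    """Tunable knobs of the extraction step.

    min_coverage: minimum unambiguous, QC-passing reads for a window to be kept.
    apply_conversion_filter: drop reads with conversion efficiency < min_conversion.
    min_base_quality: bases below this Phred floor are called ambiguous (0 = off).
    qc_exclude_analyzed_context: for non-CG analyses, also exclude the analyzed
        context's cytosines from the conversion-QC denominator.
    """

    min_coverage: int = 1
    min_conversion: float = 0.9
    apply_conversion_filter: bool = False
    min_base_quality: int = 0
    qc_exclude_analyzed_context: bool = True
    skip_flags: int = DEFAULT_SKIP_FLAGS


def read_origin_strand(read: pysam.AlignedSegment) -> str:
    """Bisulfite strand of origin: '+' (original top) or '-' (original bottom)."""
    if read.has_tag("XG"):
        tag = read.get_tag("XG")
        if tag == "CT":
            return "+"
        if tag == "GA":
            return "-"
    return "-" if read.is_reverse else "+"


def spanning_reads(
    bam: AlignmentView,
    window: AnalysisWindow,
    skip_flags: int = DEFAULT_SKIP_FLAGS,
) -> List[pysam.AlignedSegment]:
    """Alignments whose aligned reference span fully contains the window.

    In stranded mode only reads originating from the window's strand are
    returned; merged CG windows accept reads from both strands.
    """
    lo, hi = window.required_span()
    chrom = window.interval.chrom
    out = []
    for read in bam.fetch(chrom, lo, hi):
        if read.is_unmapped or (read.flag & skip_flags):
            continue
        if read.reference_start + 1 > lo or read.reference_end < hi:
            continue
        if window.strand_mode == "stranded" and read_origin_strand(read) != window.interval.strand:
            continue
        out.append(read)
    return out


def _reference_position_map(read: pysam.AlignedSegment) -> Dict[int, Optional[int]]:
    """Map 1-based reference position -> query index (None under a deletion)."""
    out: Dict[int, Optional[int]] = {}
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is not None:
            out[rpos + 1] = qpos
    return out


def _read_base(
    read: pysam.AlignedSegment,
    posmap: Dict[int, Optional[int]],
    pos: int,
    min_base_quality: int = 0,
) -> Optional[str]:
    """Base the read shows at a reference position, or None (deletion/low quality)."""
    qpos = posmap.get(pos)
    if qpos is None:
        return None
    if min_base_quality > 0:
        quals = read.query_qualities
        if quals is not None and quals[qpos] < min_base_quality:
            return None
    return read.query_sequence[qpos].upper()


def call_site(
    read: pysam.AlignedSegment,
    site: CpXSite,
    min_base_quality: int = 0,
    _posmap: Optional[Dict[int, Optional[int]]] = None,
) -> int:
    """Methylation call {0, 1, 2} of one read at one CpX site.

    Plus-strand site: C -> methylated, T -> unmethylated, anything else
    (including a deletion) -> ambiguous. Minus-strand site (reference plus
    base G): G -> methylated, A -> unmethylated, else ambiguous.
    """
    posmap = _posmap if _posmap is not None else _reference_position_map(read)
    lo, hi = site.dinucleotide_span
    if read.reference_start + 1 > lo or read.reference_end < hi:
        raise ValueError(
            f"read {read.query_name} does not span site {site.chrom}:{site.pos}{site.strand}"
        )
    base = _read_base(read, posmap, site.pos, min_base_quality)
    if site.strand == "+":
        if base == "C":
            return METHYLATED
        if base == "T":
            return UNMETHYLATED
    else:
        if base == "G":
            return METHYLATED
        if base == "A":
            return UNMETHYLATED
    return AMBIGUOUS


def _qc_cytosines(
    reference: ReferenceGenome,
    window: AnalysisWindow,
    strand: str,
    exclude_analyzed: bool = True,
) -> List[int]:
    """Reference cytosine positions eligible for the conversion-QC denominator.

    Cytosines on `strand` inside the window interval, excluding the CG
    context always, and excluding the analyzed context as well when it
    differs from CG (configurable).
    """
    iv = window.interval
    chrom_len = reference.chrom_length(iv.chrom)
    lo = max(1, iv.start - 1)
    hi = min(chrom_len, iv.end + 1)
    seq = reference.fetch(iv.chrom, lo, hi)
    ctx = window.context
    positions: List[int] = []
    for pos in range(iv.start, iv.end + 1):
        i = pos - lo
        if strand == "+":
            if seq[i] != "C":
                continue
            nxt = seq[i + 1] if i + 1 < len(seq) else "N"
            if nxt == "G":
                continue
            if exclude_analyzed and ctx != "CG" and nxt == ctx[1]:
                continue
        else:
            if seq[i] != "G":
                continue
            prv = seq[i - 1] if i - 1 >= 0 else "N"
            if prv == "C":
                continue
            if exclude_analyzed and ctx != "CG" and prv == COMPLEMENT[ctx[1]]:
                continue
        positions.append(pos)
    return positions


def conversion_efficiency(
    read: pysam.AlignedSegment,
    window: AnalysisWindow,
    reference: ReferenceGenome,
    exclude_analyzed: bool = True,
    _posmap: Optional[Dict[int, Optional[int]]] = None,
) -> float:
    """Fraction of eligible non-CpX cytosines the read shows as converted.

    Converted means T at a plus-strand C (A at a minus-strand C). Positions
    where the read shows neither the converted nor the unconverted base are
    ignored; with no assessable cytosines the read vacuously passes (1.0).
    """
    strand = read_origin_strand(read)
    positions = _qc_cytosines(reference, window, strand, exclude_analyzed)
    if not positions:
        return 1.0
    posmap = _posmap if _posmap is not None else _reference_position_map(read)
    converted_base, unconverted_base = ("T", "C") if strand == "+" else ("A", "G")
    converted = assessed = 0
    for pos in positions:
        base = _read_base(read, posmap, pos)
        if base == converted_base:
            converted += 1
            assessed += 1
        elif base == unconverted_base:
            assessed += 1
    if assessed == 0:
        return 1.0
    return converted / assessed


def _window_calls(
    read: pysam.AlignedSegment,
    window: AnalysisWindow,
    min_base_quality: int,
    posmap: Dict[int, Optional[int]],
) -> np.ndarray:
    """Calls at every window site for one read (merged mode resolves the unit
    position on the read's own strand)."""
    chrom = window.interval.chrom
    calls = np.empty(window.n_sites, dtype=np.int8)
    strand = (
        read_origin_strand(read) if window.strand_mode == "merged" else window.interval.strand
    )
    for j, pos in enumerate(window.sites):
        if window.strand_mode == "merged" and strand == "-":
            site = CpXSite(chrom, pos + 1, "-", window.context)
        else:
            site = CpXSite(chrom, pos, strand, window.context)
        calls[j] = call_site(read, site, min_base_quality, _posmap=posmap)
    return calls


def extract_window(
    bam: AlignmentView,
    reference: ReferenceGenome,
    window: AnalysisWindow,
    params: Optional[ExtractionParams] = None,
    sample_id: str = "",
) -> Union[Tuple[BinaryEpialleleMatrix, EpialleleTable], ExcludedRegionRecord]:
    """Build the binary matrix and compressed table for one window.

    Reads failing the (optional) conversion filter are dropped from the
    matrix; rows containing an ambiguous call stay in the matrix but are
    excluded from the table. Windows whose unambiguous retained read count
    falls below ``min_coverage`` are excluded with the appropriate reason.
    """
    params = params or ExtractionParams()
    reads = spanning_reads(bam, window, skip_flags=params.skip_flags)
    if not reads:
        return ExcludedRegionRecord(window.id, "no_spanning_reads")

    read_ids: List[str] = []
    rows: List[np.ndarray] = []
    strands: List[str] = []
    efficiencies: List[float] = []
    for read in reads:
        posmap = _reference_position_map(read)
        eff = conversion_efficiency(
            read, window, reference, params.qc_exclude_analyzed_context, _posmap=posmap
        )
        if params.apply_conversion_filter and eff < params.min_conversion:
            continue
        rows.append(_window_calls(read, window, params.min_base_quality, posmap))
        read_ids.append(read.query_name)
        strands.append(read_origin_strand(read))
        efficiencies.append(eff)

    if not rows:
        return ExcludedRegionRecord(window.id, "insufficient_coverage_after_qc")

    matrix = BinaryEpialleleMatrix(
        window=window,
        read_ids=read_ids,
        cells=np.vstack(rows),
        read_strands=strands,
        conversion_efficiencies=efficiencies,
    )
    n_clean = int(matrix.unambiguous_rows().sum())
    if n_clean == 0:
        return ExcludedRegionRecord(window.id, "all_reads_ambiguous")
    if n_clean < params.min_coverage:
        return ExcludedRegionRecord(window.id, "insufficient_coverage_after_qc")
    return matrix, matrix.to_table(sample_id)


@dataclass
class SampleExtraction:
    """All per-window extraction results for one sample."""

    sample_id: str
    matrices: List[BinaryEpialleleMatrix] = field(default_factory=list)
    tables: List[EpialleleTable] = field(default_factory=list)
    excluded: List[ExcludedRegionRecord] = field(default_factory=list)


def extract_sample(
    bam: AlignmentView,
    reference: ReferenceGenome,
    windows: Sequence[AnalysisWindow],
    params: Optional[ExtractionParams] = None,
    sample_id: str = "",
) -> SampleExtraction:
    """Run extract_window over a window set."""
    result = SampleExtraction(sample_id=sample_id)
    for window in windows:
        out = extract_window(bam, reference, window, params, sample_id)
        if isinstance(out, ExcludedRegionRecord):
            result.excluded.append(out)
        else:
            matrix, table = out
            result.matrices.append(matrix)
            result.tables.append(table)
    return result


def write_epiallele_tables(tables: Iterable[EpialleleTable], path: str, windows_by_id=None) -> None:
    """Write compressed tables as TSV, one row per window per epiallele.

    Rows are ordered by window id, then epiallele string, so reruns on
    identical inputs are byte-identical.
    """
    windows_by_id = windows_by_id or {}
    rows = []
    for t in sorted(tables, key=lambda t: t.window_id):
        w = windows_by_id.get(t.window_id)
        chrom, start, end = _split_window_id(t.window_id) if w is None else (
            w.interval.chrom, w.interval.start, w.interval.end,
        )
        for epiallele in sorted(t.counts):
            rows.append(
                (t.window_id, chrom, start, end, t.strand, t.sample_id, epiallele, t.counts[epiallele])
            )
    with open(path, "w") as fh:
        fh.write("window_id\tchrom\tstart\tend\tstrand\tsample_id\tepiallele\tcount\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_excluded_regions(records: Iterable[ExcludedRegionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("window_id\treason\n")
        for rec in sorted(records, key=lambda r: r.window_id):
            fh.write(f"{rec.window_id}\t{rec.reason}\n")


def _split_window_id(window_id: str) -> Tuple[str, int, int]:
    parts = window_id.rsplit("_", 3)
    return parts[0], int(parts[1]), int(parts[2])


def extract_all(
    bam: AlignmentView,
    reference: ReferenceGenome,
    windows: Sequence[AnalysisWindow],
    out_prefix: str,
    params: Optional[ExtractionParams] = None,
    sample_id: str = "",
    registry=None,
):
    """Full extraction for one sample, writing the three text outputs.

    Writes ``<prefix>.epialleles.tsv`` (compressed tables),
    ``<prefix>.summary.tsv`` (per-window summary statistics) and
    ``<prefix>.excluded.tsv`` (windows dropped, with reasons); returns the
    in-memory SampleExtraction.
    """
    from .summaries import SummaryRegistry, summary_table

    result = extract_sample(bam, reference, windows, params, sample_id)
    windows_by_id = {w.id: w for w in windows}
    write_epiallele_tables(result.tables, f"{out_prefix}.epialleles.tsv", windows_by_id)
    summary = summary_table(result.matrices, registry or SummaryRegistry.default(),
                            sample_id=sample_id)
    summary.to_csv(f"{out_prefix}.summary.tsv", sep="\t", index=False)
    write_excluded_regions(result.excluded, f"{out_prefix}.excluded.tsv")
    return result
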