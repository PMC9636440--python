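"""Analysis-window design: CpX site discovery and sliding-window tiling.

Two tiling schemes are provided. ``windows_by_site_count`` emits windows of
flexible length containing exactly *k* CpX sites, stepping one site at a
time (consecutive windows share k-1 sites); windows longer than the read
length are dropped, since an epiallele must come from a single molecule.
``windows_by_fixed_length`` slides a fixed-length window at a fixed stride
and keeps placements whose contained site count falls within user bounds.

Non-CG contexts are strand-asymmetric, so their windows are always stranded.
For CG, the two sites of a symmetric CpG unit (plus C at p, minus C at p+1)
may be merged into a single strand-independent unit keyed by p.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

from .genomeio import ReferenceGenome
from .types import CONTEXTS, AnalysisWindow, CpXSite, GenomicInterval

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def find_cpx_sites(
    reference: ReferenceGenome,
    interval: GenomicInterval,
    context: str,
) -> List[CpXSite]:
    """All CpX sites of the given context within an interval, on both strands.

    A plus-strand site at p requires reference bases ``C`` at p and the
    context's second letter at p+1. A minus-strand site at p requires ``G``
    at p and the complement of the context's second letter at p-1 (the
    dinucleotide read 5'->3' on the minus strand). For CG the minus site of
    a plus CpG at p is therefore at p+1.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}: {context!r}")
    chrom = interval.chrom
    # fetch one flanking base on each side so edge sites resolve their context
    lo = max(1, interval.start - 1)
    hi = min(reference.chrom_length(chrom), interval.end + 1)
    seq = reference.fetch(chrom, lo, hi)
    second = context[1]
    second_rc = COMPLEMENT[second]
    sites: List[CpXSite] = []
    for pos in range(interval.start, interval.end + 1):
        i = pos - lo
        base = seq[i]
        if base == "C" and i + 1 < len(seq) and seq[i + 1] == second:
            sites.append(CpXSite(chrom, pos, "+", context))
        if base == "G" and i - 1 >= 0 and seq[i - 1] == second_rc:
            sites.append(CpXSite(chrom, pos, "-", context))
    sites.sort(key=lambda s: (s.pos, s.strand))
    return sites


def merged_cg_units(sites: Sequence[CpXSite]) -> List[int]:
    """Collapse CG sites to strand-independent units keyed by the plus C position.

    A minus-strand CG site at p maps to the unit at p-1; units present on
    either strand are reported once, sorted.
    """
    units = set()
    for s in sites:
        if s.context != "CG":
            raise ValueError("merged units are only defined for the CG context")
        units.add(s.pos if s.strand == "+" else s.pos - 1)
    return sorted(units)


def _window_interval(chrom: str, positions: Sequence[int], strand: str, merged: bool) -> GenomicInterval:
    """Window interval including the second base of the terminal dinucleotide."""
    first, last = positions[0], positions[-1]
    if merged or strand == "+":
        return GenomicInterval(chrom, first, last + 1, "*" if merged else "+")
    # minus-strand sites: second context base sits at pos - 1
    return GenomicInterval(chrom, first - 1, last, "-")


def windows_by_site_count(
    sites: Sequence[CpXSite],
    k: int,
    max_len: int,
    strand_mode: str = "stranded",
) -> List[AnalysisWindow]:
    """Flexible-length windows of exactly k sites, stepping one site at a time.

    In stranded mode `sites` must come from a single chromosome and strand;
    in merged mode (CG only) they may span both strands and are collapsed to
    CpG units first. Windows whose interval exceeds ``max_len`` bp (the read
    length cap) are dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sites:
        return []
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ValueError("sites must come from a single chromosome")
    chrom = chroms.pop()
    context = sites[0].context

    if strand_mode == "merged":
        if context != "CG":
            raise ValueError("merged strand mode is only defined for the CG context")
        positions = merged_cg_units(sites)
        strand = "*"
    else:
        strands = {s.strand for s in sites}
        if len(strands) > 1:
            raise ValueError("stranded windows require sites from a single strand")
        strand = strands.pop()
        positions = sorted(s.pos for s in sites)

    windows: List[AnalysisWindow] = []
    for j in range(len(positions) - k + 1):
        chunk = positions[j : j + k]
        interval = _window_interval(chrom, chunk, strand, strand_mode == "merged")
        if len(interval) > max_len:
            continue
        windows.append(
            AnalysisWindow(interval, context, tuple(chunk), strand_mode=strand_mode)
        )
    return windows


def windows_by_fixed_length(
    sites: Sequence[CpXSite],
    region: GenomicInterval,
    win_len: int,
    step: int,
    min_sites: int,
    max_sites: int,
    strand_mode: str = "stranded",
) -> List[AnalysisWindow]:
    """Fixed-length windows tiling a region at a fixed stride.

    A placement is kept iff the number of contained sites lies in
    [min_sites, max_sites]; each kept window records exactly the site
    positions falling inside its interval.
    """
    if win_len < 2:
        raise ValueError("win_len must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not (1 <= min_sites <= max_sites):
        raise ValueError("need 1 <= min_sites <= max_sites")

    context = sites[0].context if sites else "CG"
    if strand_mode == "merged":
        if sites and context != "CG":
            raise ValueError("merged strand mode is only defined for the CG context")
        positions = merged_cg_units(sites)
        strand = "*"
    else:
        strands = {s.strand for s in sites}
        if len(strands) > 1:
            raise ValueError("stranded windows require sites from a single strand")
        strand = strands.pop() if strands else "+"
        positions = sorted(s.pos for s in sites)

    windows: List[AnalysisWindow] = []
    start = region.start
    while start + win_len - 1 <= region.end:
        end = start + win_len - 1
        inside = tuple(p for p in positions if start <= p <= end)
        if min_sites <= len(inside) <= max_sites:
            interval = GenomicInterval(region.chrom, start, end, strand if strand_mode == "stranded" else "*")
            windows.append(AnalysisWindow(interval, context, inside, strand_mode=strand_mode))
        start += step
    return windows


def design_windows(
    reference: ReferenceGenome,
    regions: Iterable[GenomicInterval],
    context: str,
    scheme: str = "site_count",
    strand_mode: str = "stranded",
    k: int = 4,
    max_len: int = 100,
    win_len: int = 70,
    step: int = 35,
    min_sites: int = 1,
    max_sites: int = 50,
) -> List[AnalysisWindow]:
    """Design analysis windows over a set of covered regions.

    Site-count windows never straddle a covered-region boundary (all k sites
    of a window come from the same region, so coverage is guaranteed).
    Stranded mode emits separate plus- and minus-strand window sets.
    """
    if scheme not in ("site_count", "fixed_length"):
        raise ValueError(f"unknown window scheme {scheme!r}")
    if strand_mode == "merged" and context != "CG":
        raise ValueError("merged strand mode is only defined for the CG context")
    windows: List[AnalysisWindow] = []
    for region in regions:
        sites = find_cpx_sites(reference, region, context)
        if not sites:
            continue
        if strand_mode == "merged":
            groups = [sites]
        else:
            groups = [
                [s for s in sites if s.strand == "+"],
                [s for s in sites if s.strand == "-"],
            ]
        for group in groups:
            if not group:
                continue
            if scheme == "site_count":
                windows.extend(windows_by_site_count(group, k, max_len, strand_mode=strand_mode))
            else:
                windows.extend(
                    windows_by_fixed_length(
                        group, region, win_len, step, min_sites, max_sites, strand_mode=strand_mode
                    )
                )
    windows.sort(key=lambda w: (w.interval.chrom, w.interval.start, w.interval.strand))
    return windows


def export_windows_bed(windows: Iterable[AnalysisWindow], path: str) -> None:
    """Write windows as BED6 (0-based half-open; name = window id)."""
    with open(path, "w") as fh:
        for w in windows:
            iv = w.interval
            strand = iv.strand if iv.strand != "*" else "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{w.id}\t{w.n_sites}\t{strand}\n")
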