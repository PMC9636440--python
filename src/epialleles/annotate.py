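"""Gene annotation of analysis windows.

Each window is associated with the gene whose transcription start site (TSS)
is closest to the window midpoint, and labeled with a functional-domain
category by precedence: Promoter > 5' UTR > 3' UTR > Exonic > Intronic >
Distal intergenic. A window is a promoter hit when its midpoint lies within
``promoter_flank`` bp of some TSS (default 1000 bp; configurable). Distances
to the TSS are signed relative to gene orientation: negative upstream.

Gene models come from a GTF/GFF3 file (gene/exon/UTR features) or BED12,
where exon blocks and the thick (CDS) interval define exons and UTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .types import AnalysisWindow

logger = logging.getLogger(__name__)

CATEGORIES = ("Promoter", "5' UTR", "3' UTR", "Exonic", "Intronic", "Distal intergenic")


@dataclass
class GeneModel:
    """One gene: span, strand, TSS, and exon/UTR intervals (1-based inclusive)."""

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def signed_tss_distance(self, pos: int) -> int:
        """Distance from TSS to pos; negative when pos is upstream of the gene."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def read_bed12(path: str) -> List[GeneModel]:
    """Parse gene models from BED12 (blocks = exons, thick interval = CDS)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, cstart, cend, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            start, end = cstart + 1, cend  # to 1-based inclusive
            exons: List[Tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(cstart + o + 1, cstart + o + s) for s, o in zip(sizes, offsets)]
            else:
                exons = [(start, end)]
            utr5: List[Tuple[int, int]] = []
            utr3: List[Tuple[int, int]] = []
            if len(f) >= 8:
                thick_start, thick_end = int(f[6]) + 1, int(f[7])
                if thick_end >= thick_start:  # coding gene
                    before = _clip_exons(exons, start, thick_start - 1)
                    after = _clip_exons(exons, thick_end + 1, end)
                    utr5, utr3 = (before, after) if strand == "+" else (after, before)
            genes.append(GeneModel(name, chrom, strand, start, end, exons, utr5, utr3))
    return genes


def _clip_exons(exons: Sequence[Tuple[int, int]], lo: int, hi: int) -> List[Tuple[int, int]]:
    if hi < lo:
        return []
    out = []
    for a, b in exons:
        a2, b2 = max(a, lo), min(b, hi)
        if a2 <= b2:
            out.append((a2, b2))
    return out


_UTR5_TYPES = {"five_prime_utr", "five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR"}


def read_gtf(path: str) -> List[GeneModel]:
    """Parse gene models from GTF or GFF3 (gene, exon, UTR features)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        symbol = _first_attr(gene, ("gene_name", "Name", "gene_id", "ID")) or gene.id
        model = GeneModel(symbol, gene.seqid, gene.strand, gene.start, gene.end)
        for exon in db.children(gene, featuretype="exon"):
            model.exons.append((exon.start, exon.end))
        for ft in _UTR5_TYPES:
            for utr in db.children(gene, featuretype=ft):
                model.utr5.append((utr.start, utr.end))
        for ft in _UTR3_TYPES:
            for utr in db.children(gene, featuretype=ft):
                model.utr3.append((utr.start, utr.end))
        if not model.exons:
            model.exons = [(gene.start, gene.end)]
        genes.append(model)
    return genes


def _first_attr(feature, keys) -> Optional[str]:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_gene_models(path: str) -> List[GeneModel]:
    """Dispatch on file extension: .bed -> BED12, else GTF/GFF3."""
    if path.endswith((".bed", ".bed12")):
        return read_bed12(path)
    return read_gtf(path)


def _in_any(pos: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def annotate_regions(
    windows: Union[pd.DataFrame, Sequence[AnalysisWindow]],
    genes: Sequence[GeneModel],
    promoter_flank: int = 1000,
) -> pd.DataFrame:
    """Annotate windows with their closest gene and functional category.

    Returns a DataFrame with window_id, gene, distance_to_tss (signed bp,
    negative upstream of the gene), and category. Windows on chromosomes
    with no gene get 'Distal intergenic' with no gene and a warning.
    """
    if not genes:
        raise ValueError("empty gene model list")
    if promoter_flank <= 0:
        raise ValueError("promoter_flank must be positive")
    logger.info("annotating with promoter flank = %d bp around the TSS", promoter_flank)
    if isinstance(windows, pd.DataFrame):
        frame = windows[["window_id", "chrom", "start", "end"]]
    else:
        frame = pd.DataFrame(
            [(w.id, w.interval.chrom, w.interval.start, w.interval.end) for w in windows],
            columns=["window_id", "chrom", "start", "end"],
        )
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for rec in frame.itertuples(index=False):
        mid = (rec.start + rec.end) // 2
        candidates = by_chrom.get(rec.chrom, [])
        if not candidates:
            logger.warning("no gene models on chromosome %s; window %s left intergenic",
                           rec.chrom, rec.window_id)
            rows.append((rec.window_id, None, None, "Distal intergenic"))
            continue
        nearest = min(candidates, key=lambda g: (abs(mid - g.tss), g.symbol))
        distance = nearest.signed_tss_distance(mid)
        if abs(mid - nearest.tss) <= promoter_flank:
            category = "Promoter"
        elif any(_in_any(mid, g.utr5) for g in candidates):
            category = "5' UTR"
        elif any(_in_any(mid, g.utr3) for g in candidates):
            category = "3' UTR"
        elif any(_in_any(mid, g.exons) for g in candidates):
            category = "Exonic"
        elif any(g.start <= mid <= g.end for g in candidates):
            category = "Intronic"
        else:
            category = "Distal intergenic"
        rows.append((rec.window_id, nearest.symbol, distance, category))
    return pd.DataFrame(rows, columns=["window_id", "gene", "distance_to_tss", "category"])
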