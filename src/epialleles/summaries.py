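"""Per-window summary statistics over the binary epiallele matrix.

The default registry computes, per window: the number of CpX sites (n), the
number of spanning unambiguous reads (c), the mean distance between
consecutive sites in bp (d), the number of observed epiallele species, the
number of singleton species, the most frequent epiallele, the Shannon
entropy of the species frequencies in bits, and the average methylation
a = m / (n * c) where m is the number of methylated cells.

All statistics are computed after the ambiguity and conversion-QC
exclusions, so c always equals the total of the compressed epiallele table.
The registry is extensible: user functions take the matrix and return a
scalar; a function that raises yields a missing value for that window and a
logged warning, and the run continues.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AMBIGUOUS, METHYLATED, BinaryEpialleleMatrix, EpialleleTable

logger = logging.getLogger(__name__)


def mean_site_distance(positions: Sequence[int]) -> float:
    """Mean distance in bp between consecutive CpX sites.

    Mean of the absolute gaps |p_{i+1} - p_i| over the n-1 consecutive pairs.
    Undefined (NaN) for fewer than two positions.
    """
    if len(positions) < 2:
        return float("nan")
    gaps = np.abs(np.diff(np.asarray(positions, dtype=float)))
    return float(gaps.mean())


def shannon_entropy(counts: Dict[str, int]) -> float:
    """Shannon entropy (bits) of the epiallele species frequencies.

    H = -sum_k p_k log2 p_k over observed species; 0 when all reads carry
    the same epiallele, up to n bits when all 2^n species are equally
    frequent. 0 * log 0 is taken as 0 (absent species contribute nothing).
    """
    total = sum(counts.values())
    if total < 1:
        raise ValueError("entropy of an empty epiallele table is undefined")
    h = 0.0
    for count in counts.values():
        if count > 0:
            p = count / total
            h -= p * math.log2(p)
    return h


def average_methylation(matrix: BinaryEpialleleMatrix) -> float:
    """Average methylation a = m / (n * c) over unambiguous rows."""
    clean = matrix.cells[matrix.unambiguous_rows()]
    if clean.shape[0] == 0:
        raise ValueError("no unambiguous reads; average methylation undefined")
    return float((clean == METHYLATED).sum() / clean.size)


def species_counts(counts: Dict[str, int]) -> Tuple[int, int, str]:
    """(number of species, number of singletons, most frequent epiallele).

    Ties for the top epiallele break to the lexicographically smallest string.
    """
    if not counts:
        raise ValueError("empty epiallele table")
    n_species = len(counts)
    singletons = sum(1 for c in counts.values() if c == 1)
    top = min(counts, key=lambda k: (-counts[k], k))
    return n_species, singletons, top


def _table_counts(matrix: BinaryEpialleleMatrix) -> Dict[str, int]:
    return matrix.to_table().counts


class SummaryRegistry:
    """Ordered, named registry of per-window statistics.

    Each entry maps a column name to a function of the binary matrix. The
    default registry reproduces the predefined statistic set; `register`
    appends user statistics (duplicate names are an error).
    """

    def __init__(self) -> None:
        self._stats: Dict[str, Callable[[BinaryEpialleleMatrix], object]] = {}

    def register(self, name: str, fn: Callable[[BinaryEpialleleMatrix], object]) -> "SummaryRegistry":
        if name in self._stats:
            raise ValueError(f"statistic {name!r} already registered")
        self._stats[name] = fn
        return self

    @property
    def names(self) -> List[str]:
        return list(self._stats)

    def compute(self, matrix: BinaryEpialleleMatrix) -> Dict[str, object]:
        out: Dict[str, object] = {}
        for name, fn in self._stats.items():
            try:
                out[name] = fn(matrix)
            except Exception as exc:  # robustness: one bad stat must not kill the run
                logger.warning("statistic %r failed on window %s: %s", name, matrix.window.id, exc)
                out[name] = float("nan")
        return out

    @classmethod
    def default(cls) -> "SummaryRegistry":
        reg = cls()
        reg.register("n_cpx", lambda m: m.n_sites)
        reg.register("n_reads", lambda m: int(m.unambiguous_rows().sum()))
        reg.register("mean_dist", lambda m: mean_site_distance(m.window.sites))
        reg.register("n_species", lambda m: species_counts(_table_counts(m))[0])
        reg.register("singletons", lambda m: species_counts(_table_counts(m))[1])
        reg.register("top_epiallele", lambda m: species_counts(_table_counts(m))[2])
        reg.register("shannon", lambda m: shannon_entropy(_table_counts(m)))
        reg.register("mean_meth", average_methylation)
        return reg


def summary_record(matrix: BinaryEpialleleMatrix, registry: Optional[SummaryRegistry] = None) -> Dict[str, object]:
    """One summary row (window coordinates + every registered statistic)."""
    registry = registry or SummaryRegistry.default()
    iv = matrix.window.interval
    row: Dict[str, object] = {
        "window_id": matrix.window.id,
        "chrom": iv.chrom,
        "start": iv.start,
        "end": iv.end,
        "strand": iv.strand,
    }
    row.update(registry.compute(matrix))
    return row


def summary_table(
    matrices: Sequence[BinaryEpialleleMatrix],
    registry: Optional[SummaryRegistry] = None,
    sample_id: Optional[str] = None,
) -> pd.DataFrame:
    """Summary statistics for a set of windows as a DataFrame (one row each)."""
    registry = registry or SummaryRegistry.default()
    rows = [summary_record(m, registry) for m in matrices]
    columns = ["window_id", "chrom", "start", "end", "strand"] + registry.names
    df = pd.DataFrame(rows, columns=columns)
    if sample_id is not None:
        df.insert(1, "sample_id", sample_id)
    return df.sort_values("window_id", kind="stable").reset_index(drop=True)
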