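"""Synthetic bisulfite-sequencing data with known epiallele ground truth.

The simulator builds a reference whose background alternates A/T so the only
cytosines are the ones planted on purpose: analyzed CpX sites, and optional
"QC cytosines" outside the analyzed (and CG) context whose conversion status
exercises the bisulfite-conversion check. It then writes per-sample sorted,
indexed BAM files whose reads are drawn from per-sample, per-strand
epiallele mixtures, with configurable conversion-failure and SNV rates, plus
a per-read truth table, realized epiallele counts, and a sample-metadata
table.

Reads are single-end with a full-length match CIGAR, stacked end-to-end over
each region (so every read spans every window of the region); an optional
mode adds one read with a 1-bp deletion at the first site to exercise the
indel-to-ambiguous path. Epiallele strings are ordered by ascending
plus-strand coordinate on both strands. Everything is driven by a single
seed and is bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Faidx

from .regions import COMPLEMENT
from .types import CONTEXTS

_MAPQ = 42


@dataclass
class RegionSim:
    """One simulated region: planted site and QC-cytosine positions.

    ``plus_sites`` are plus-strand C positions of the analyzed context; for
    CG the paired minus-strand sites sit at pos + 1 automatically, so
    ``minus_sites`` is only given for non-CG contexts. QC cytosines are
    planted outside both the CG and the analyzed context.
    """

    name: str
    chrom: str
    start: int
    length: int
    context: str = "CG"
    plus_sites: Tuple[int, ...] = ()
    minus_sites: Tuple[int, ...] = ()
    qc_sites_plus: Tuple[int, ...] = ()
    qc_sites_minus: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}")
        if self.context == "CG":
            if self.minus_sites:
                raise ValueError("CG minus sites are implied at plus_site + 1")
            self.minus_sites = tuple(p + 1 for p in self.plus_sites)
        for pos in (*self.plus_sites, *self.minus_sites, *self.qc_sites_plus, *self.qc_sites_minus):
            if not (self.start + 1 <= pos <= self.end - 1):
                raise ValueError(
                    f"position {pos} (with its context base) outside region "
                    f"{self.name} [{self.start}, {self.end}]"
                )

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def sites_on(self, strand: str) -> Tuple[int, ...]:
        return self.plus_sites if strand == "+" else self.minus_sites


@dataclass
class SampleSim:
    """One simulated sample: group label, mixtures, noise rates.

    ``mixtures`` maps region name -> epiallele string -> probability, used
    for plus-strand molecules (and, for CG, as the per-unit pattern of minus
    molecules too); ``mixtures_minus`` overrides the minus strand where
    needed (mandatory for non-CG regions whose two strands have different
    site counts).
    """

    sample_id: str
    group: str
    mixtures: Dict[str, Dict[str, float]] = field(default_factory=dict)
    mixtures_minus: Dict[str, Dict[str, float]] = field(default_factory=dict)
    reads_per_strand: int = 30
    conversion_failure_rate: float = 0.0
    snv_rate: float = 0.0
    covariates: Dict[str, float] = field(default_factory=dict)

    def mixture_for(self, region: RegionSim, strand: str) -> Dict[str, float]:
        if strand == "-" and region.name in self.mixtures_minus:
            mix = self.mixtures_minus[region.name]
        else:
            mix = self.mixtures[region.name]
        n = len(region.sites_on(strand))
        for key in mix:
            if len(key) != n or set(key) - {"0", "1"}:
                raise ValueError(
                    f"mixture epiallele {key!r} does not match the {n} "
                    f"{strand}-strand sites of region {region.name}"
                )
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"mixture probabilities must sum to 1 in region {region.name}")
        return mix


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset."""

    regions: List[RegionSim]
    samples: List[SampleSim]
    seed: int = 0
    add_deletion_read: bool = False

    def chrom_lengths(self) -> Dict[str, int]:
        lengths: Dict[str, int] = {}
        for r in self.regions:
            lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end + 50)
        return lengths


def _qc_second_base(context: str) -> str:
    # the planted QC dinucleotide must be neither CG nor the analyzed context
    return "A" if context == "CT" else "T"


def build_reference(spec: SimulationSpec, fasta_path: str) -> str:
    """Write the FASTA (+ .fai) implied by the spec; returns the path.

    The background carries no C or G, so site discovery over any simulated
    region recovers exactly the planted sites.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = {c: rng.choice(list("AT"), size=n) for c, n in spec.chrom_lengths().items()}
    planted: Dict[str, set] = {c: set() for c in chroms}

    def plant(chrom: str, pos: int, base: str) -> None:
        if pos in planted[chrom] and chroms[chrom][pos - 1] != base:
            raise ValueError(f"overlapping planted dinucleotides at {chrom}:{pos}")
        chroms[chrom][pos - 1] = base
        planted[chrom].add(pos)

    for r in spec.regions:
        second = r.context[1]
        for p in r.plus_sites:
            plant(r.chrom, p, "C")
            plant(r.chrom, p + 1, second)
        if r.context != "CG":
            for q in r.minus_sites:
                plant(r.chrom, q, "G")
                plant(r.chrom, q - 1, COMPLEMENT[second])
        qc2 = _qc_second_base(r.context)
        for p in r.qc_sites_plus:
            plant(r.chrom, p, "C")
            plant(r.chrom, p + 1, qc2)
        for q in r.qc_sites_minus:
            plant(r.chrom, q, "G")
            plant(r.chrom, q - 1, COMPLEMENT[qc2])

    with open(fasta_path, "w") as fh:
        for chrom in sorted(chroms):
            fh.write(f">{chrom}\n")
            seq = "".join(chroms[chrom])
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    Faidx(fasta_path, rebuild=True)
    return fasta_path


def _mutate(seq: List[str], pos: int, origin: int, base: str) -> None:
    seq[pos - origin] = base


def _simulate_read_sequence(
    ref_seq: str,
    region: RegionSim,
    strand: str,
    pattern: str,
    rng: np.random.Generator,
    conversion_failure_rate: float,
    snv_rate: float,
) -> Tuple[str, bool, int]:
    """Read bases over the region span (plus orientation).

    Returns (sequence, has_snv, n_conversion_failures). Bisulfite conversion
    acts on the originating strand only: plus molecules convert plus-strand
    Cs (C -> T), minus molecules convert minus-strand Cs (G -> A in plus
    orientation).
    """
    seq = list(ref_seq)
    origin = region.start
    sites = region.sites_on(strand)
    state = dict(zip(sites, pattern))
    meth_base, unmeth_base = ("C", "T") if strand == "+" else ("G", "A")
    for pos in sites:
        _mutate(seq, pos, origin, meth_base if state[pos] == "1" else unmeth_base)
    if region.context == "CG" and strand == "-":
        # the plus C of each CpG unit is untouched on a minus molecule
        pass
    n_failures = 0
    qc_sites = region.qc_sites_plus if strand == "+" else region.qc_sites_minus
    for pos in qc_sites:
        if rng.random() < conversion_failure_rate:
            _mutate(seq, pos, origin, meth_base)  # unconverted: still C (G on minus)
            n_failures += 1
        else:
            _mutate(seq, pos, origin, unmeth_base)
    has_snv = False
    if snv_rate > 0:
        disruptive = "G" if strand == "+" else "C"
        for pos in sites:
            if rng.random() < snv_rate:
                _mutate(seq, pos, origin, disruptive)
                has_snv = True
    return "".join(seq), has_snv, n_failures


@dataclass
class SimulatedDataset:
    """Paths and ground truth of one simulated dataset."""

    fasta: str
    bams: Dict[str, str]
    truth_reads: pd.DataFrame
    truth_counts: pd.DataFrame
    metadata: pd.DataFrame
    spec: SimulationSpec


def simulate_dataset(spec: SimulationSpec, outdir: str) -> SimulatedDataset:
    """Build reference and per-sample BAMs; write truth and metadata TSVs."""
    os.makedirs(outdir, exist_ok=True)
    fasta = build_reference(spec, os.path.join(outdir, "reference.fa"))
    rng = np.random.default_rng(spec.seed + 1)
    lengths = spec.chrom_lengths()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": lengths[c]} for c in sorted(lengths)],
    }
    truth_rows = []
    bams: Dict[str, str] = {}
    for sample in spec.samples:
        records = []
        for region in spec.regions:
            ref_seq = None
            for strand in ("+", "-"):
                sites = region.sites_on(strand)
                if not sites:
                    continue
                mix = sample.mixture_for(region, strand)
                keys = sorted(mix)
                probs = np.array([mix[k] for k in keys])
                draws = rng.choice(len(keys), size=sample.reads_per_strand, p=probs)
                if ref_seq is None:
                    ref_seq = _read_reference(fasta, region)
                for i, ki in enumerate(draws):
                    pattern = keys[ki]
                    seq, has_snv, n_fail = _simulate_read_sequence(
                        ref_seq, region, strand, pattern, rng,
                        sample.conversion_failure_rate, sample.snv_rate,
                    )
                    name = f"{sample.sample_id}_{region.name}_{'p' if strand == '+' else 'm'}_{i}"
                    records.append((region, strand, name, seq, f"{region.length}M"))
                    truth_rows.append((
                        sample.sample_id, region.name, strand, name, pattern,
                        has_snv, n_fail, False,
                    ))
            if spec.add_deletion_read and region.plus_sites:
                name = f"{sample.sample_id}_{region.name}_del"
                seq, cigar = _deletion_read(ref_seq, region)
                records.append((region, "+", name, seq, cigar))
                truth_rows.append((
                    sample.sample_id, region.name, "+", name, "", False, 0, True,
                ))
        bam_path = os.path.join(outdir, f"{sample.sample_id}.bam")
        _write_bam(bam_path, header, records)
        bams[sample.sample_id] = bam_path

    truth_reads = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "region", "strand", "read_id", "epiallele",
                 "has_snv", "n_conversion_failures", "has_deletion"],
    )
    clean = truth_reads[~truth_reads["has_deletion"]]
    truth_counts = (
        clean.groupby(["sample_id", "region", "strand", "epiallele"], sort=True)
        .size().rename("count").reset_index()
    )
    metadata = pd.DataFrame(
        [{"sample_id": s.sample_id, "group": s.group, **s.covariates} for s in spec.samples]
    )
    truth_reads.to_csv(os.path.join(outdir, "truth_reads.tsv"), sep="\t", index=False)
    truth_counts.to_csv(os.path.join(outdir, "truth_counts.tsv"), sep="\t", index=False)
    metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    return SimulatedDataset(fasta, bams, truth_reads, truth_counts, metadata, spec)


def _read_reference(fasta: str, region: RegionSim) -> str:
    with pysam.FastaFile(fasta) as fh:
        return fh.fetch(region.chrom, region.start - 1, region.end).upper()


def _deletion_read(ref_seq: str, region: RegionSim) -> Tuple[str, str]:
    """A plus-strand read with a 1-bp deletion at the first plus site."""
    pos = region.plus_sites[0]
    offset = pos - region.start  # 0-based within region
    seq = list(ref_seq)
    # fully converted, unmethylated elsewhere
    for p in region.plus_sites:
        if p != pos:
            seq[p - region.start] = "T"
    for p in region.qc_sites_plus:
        seq[p - region.start] = "T"
    del seq[offset]
    cigar = f"{offset}M1D{region.length - offset - 1}M"
    return "".join(seq), cigar


def _write_bam(path: str, header: dict, records) -> None:
    tmp = path + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        chrom_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for region, strand, name, seq, cigar in records:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0 if strand == "+" else 16
            a.reference_id = chrom_ids[region.chrom]
            a.reference_start = region.start - 1
            a.mapping_quality = _MAPQ
            a.cigarstring = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("XG", "CT" if strand == "+" else "GA")
            out.write(a)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)


def reverse_complement_dataset(ds: SimulatedDataset, outdir: str) -> Dict[str, str]:
    """Mirror a simulated dataset onto the reverse-complemented genome.

    Every chromosome is reverse-complemented and every read remapped to the
    mirrored coordinates, with its sequence reverse-complemented and its
    orientation and XG strand-of-origin tag flipped — so molecules that
    originated from the minus strand become plus-strand molecules on the
    mirrored genome. Returns {"fasta": path, <sample_id>: bam path, ...};
    used for strand-consistency checks.
    """
    os.makedirs(outdir, exist_ok=True)
    rc = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    with pysam.FastaFile(ds.fasta) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        seqs = {c: fh.fetch(c) for c in fh.references}
    fasta_path = os.path.join(outdir, "reference_rc.fa")
    with open(fasta_path, "w") as out:
        for chrom in sorted(seqs):
            out.write(f">{chrom}\n")
            mirrored = "".join(rc[b] for b in reversed(seqs[chrom].upper()))
            for i in range(0, len(mirrored), 70):
                out.write(mirrored[i : i + 70] + "\n")
    Faidx(fasta_path, rebuild=True)

    out_paths = {"fasta": fasta_path}
    for sample_id, bam_path in ds.bams.items():
        dest = os.path.join(outdir, f"{sample_id}_rc.bam")
        tmp = dest + ".unsorted"
        with pysam.AlignmentFile(bam_path, "rb") as src:
            header = src.header.to_dict()
            with pysam.AlignmentFile(tmp, "wb", header=header) as out:
                for read in src.fetch():
                    length = lengths[read.reference_name]
                    a = pysam.AlignedSegment()
                    a.query_name = read.query_name
                    a.query_sequence = "".join(
                        rc[b] for b in reversed(read.query_sequence.upper())
                    )
                    a.flag = read.flag ^ 0x10
                    a.reference_id = read.reference_id
                    a.reference_start = length - read.reference_end
                    a.mapping_quality = read.mapping_quality
                    a.cigartuples = list(reversed(read.cigartuples))
                    a.query_qualities = read.query_qualities[::-1]
                    xg = read.get_tag("XG") if read.has_tag("XG") else "CT"
                    a.set_tag("XG", "GA" if xg == "CT" else "CT")
                    out.write(a)
        pysam.sort("-o", dest, tmp)
        os.remove(tmp)
        pysam.index(dest)
        out_paths[sample_id] = dest
    return out_paths


def default_spec(
    n_regions: int = 5,
    samples_per_group: int = 3,
    groups: Sequence[str] = ("A", "B"),
    context: str = "CG",
    n_sites: int = 2,
    reads_per_strand: int = 30,
    mixtures_by_group: Optional[Dict[str, Dict[str, float]]] = None,
    conversion_failure_rate: float = 0.0,
    snv_rate: float = 0.0,
    seed: int = 0,
) -> SimulationSpec:
    """A ready-made spec: identical regions on one chromosome, one mixture
    per group applied to every region and strand."""
    regions = []
    for i in range(n_regions):
        start = 100 + i * 200
        gap = 12
        plus = tuple(start + 20 + j * gap for j in range(n_sites))
        qc = tuple(start + 26 + j * gap for j in range(n_sites))
        regions.append(RegionSim(
            name=f"r{i}", chrom="chrSim", start=start, length=100, context=context,
            plus_sites=plus,
            minus_sites=() if context == "CG" else tuple(p + 4 for p in qc),
            qc_sites_plus=qc,
            qc_sites_minus=tuple(p + 10 for p in plus) if context == "CG" else (),
        ))
    if mixtures_by_group is None:
        half = {"0" * n_sites: 0.5, "1" * n_sites: 0.5}
        mixtures_by_group = {g: half for g in groups}
    samples = []
    for g in groups:
        for j in range(samples_per_group):
            sid = f"{g}{j + 1}"
            mix = mixtures_by_group[g]
            samples.append(SampleSim(
                sample_id=sid, group=g,
                mixtures={r.name: dict(mix) for r in regions},
                mixtures_minus={
                    r.name: dict(mix) for r in regions
                } if context != "CG" else {},
                reads_per_strand=reads_per_strand,
                conversion_failure_rate=conversion_failure_rate,
                snv_rate=snv_rate,
            ))
    return SimulationSpec(regions=regions, samples=samples, seed=seed)
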