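"""Shared fixtures: small simulated datasets and BAM-building helpers."""

from __future__ import annotations

import os

import numpy as np
import pysam
import pytest

from epialleles import load_reference, open_alignments
from epialleles.simulate import SampleSim, SimulationSpec, default_spec, simulate_dataset


@pytest.fixture(scope="session")
def cg_dataset(tmp_path_factory):
    """CG dataset, two groups with different epiallele mixtures, zero noise."""
    spec = default_spec(
        n_regions=3,
        samples_per_group=3,
        n_sites=2,
        seed=11,
        mixtures_by_group={
            "A": {"00": 0.7, "11": 0.3},
            "B": {"11": 0.7, "00": 0.3},
        },
    )
    outdir = tmp_path_factory.mktemp("cg_sim")
    return simulate_dataset(spec, str(outdir))


@pytest.fixture(scope="session")
def cg_reference(cg_dataset):
    return load_reference(cg_dataset.fasta)


def make_bam(path, chrom_lengths, reads):
    """Write a tiny sorted+indexed BAM.

    `reads` is a list of dicts with keys: name, chrom, start (1-based), seq,
    cigar (optional, default full match), strand ('+'/'-'), xg (optional tag).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())],
    }
    chrom_ids = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["name"]
            a.query_sequence = r["seq"]
            a.flag = 16 if r.get("strand", "+") == "-" else 0
            a.reference_id = chrom_ids[r["chrom"]]
            a.reference_start = r["start"] - 1
            a.mapping_quality = 40
            a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            a.query_qualities = pysam.qualitystring_to_array(
                r.get("quals", "I" * len(r["seq"]))
            )
            if "xg" in r:
                a.set_tag("XG", r["xg"])
            elif r.get("strand", "+") == "-":
                a.set_tag("XG", "GA")
            else:
                a.set_tag("XG", "CT")
            out.write(a)
    pysam.sort("-o", str(path), tmp)
    os.remove(tmp)
    pysam.index(str(path))
    return str(path)


def write_fasta(path, sequences):
    """Write a FASTA (+ index) from a {chrom: sequence} dict."""
    from pyfaidx import Faidx

    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n{sequences[chrom]}\n")
    Faidx(str(path), rebuild=True)
    return str(path)
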