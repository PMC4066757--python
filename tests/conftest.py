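"""Shared fixtures: tiny libraries, synthetic reads, and programmatic BAMs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from tepool.formats_io import AlignedRead, TELibrary


def make_read(
    name: str = "r1",
    contig: str | None = "chr1",
    start: int = 0,
    end: int = 90,
    strand: str = "+",
    mapq: int = 60,
    is_unique: bool = True,
    is_mapped: bool = True,
    is_read1: bool = True,
    mate_contig: str | None = "chr1",
    mate_start: int = 300,
    mate_strand: str = "-",
    mate_mapped: bool = True,
    clip_left: int = 0,
    clip_right: int = 0,
    clip_left_seq: str = "",
    clip_right_seq: str = "",
    seq: str = "",
) -> AlignedRead:
    if not seq:
        seq = "A" * max(end - start + clip_left + clip_right, 1)
    return AlignedRead(
        name=name, contig=contig, start=start, end=end, strand=strand,
        mapq=mapq, is_unique=is_unique, is_mapped=is_mapped, is_read1=is_read1,
        mate_contig=mate_contig, mate_start=mate_start, mate_strand=mate_strand,
        mate_mapped=mate_mapped, clip_left=clip_left, clip_right=clip_right,
        clip_left_seq=clip_left_seq, clip_right_seq=clip_right_seq, seq=seq,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_library(rng) -> TELibrary:
    return TELibrary(
        {
            "alpha": random_seq(rng, 500),
            "beta": random_seq(rng, 800),
            "gamma": random_seq(rng, 300),
        }
    )


def write_bam(
    path: Path,
    records: list[dict],
    contigs: dict[str, int] = None,
) -> Path:
    """Write a coordinate-sorted, indexed BAM from record dicts.

    Each dict may carry: name, flag, contig, start, mapq, cigar, seq,
    mate_contig, mate_start, tlen.
    """
    contigs = contigs or {"chr1": 100_000}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
    }
    names = list(contigs)
    unsorted = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rec["name"]
            a.flag = rec.get("flag", 0)
            a.reference_id = (
                names.index(rec["contig"]) if rec.get("contig") else -1
            )
            a.reference_start = rec.get("start", -1)
            a.mapping_quality = rec.get("mapq", 60)
            if rec.get("cigar"):
                a.cigarstring = rec["cigar"]
            seq = rec.get("seq")
            if seq:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            mate = rec.get("mate_contig")
            a.next_reference_id = names.index(mate) if mate else -1
            a.next_reference_start = rec.get("mate_start", -1)
            a.template_length = rec.get("tlen", 0)
            bam.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    Path(unsorted).unlink()
    return path
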