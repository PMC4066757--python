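"""Thin wrapper around an external short-read aligner (bwa) for the
simulation and evaluation workflow.

Read mapping is upstream of the caller — any aligner producing
coordinate-sorted BAM with soft clips and mapping qualities works.  These
helpers script the bwa-mem calls the benchmark harness and tests use.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pysam


def require_bwa() -> str:
    exe = shutil.which("bwa")
    if exe is None:
        raise RuntimeError(
            "bwa not found on PATH; mapping is required for the simulation harness"
        )
    return exe


def bwa_index(fasta: str | Path) -> None:
    subprocess.run(
        [require_bwa(), "index", str(fasta)],
        check=True,
        capture_output=True,
    )


def bwa_mem(
    fasta: str | Path,
    fq1: str | Path,
    fq2: str | Path,
    out_bam: str | Path,
    threads: int = 1,
) -> Path:
    """Map a read pair set and produce a coordinate-sorted, indexed BAM."""
    out_bam = Path(out_bam)
    with tempfile.NamedTemporaryFile(
        suffix=".sam", dir=out_bam.parent, delete=False
    ) as tmp:
        sam_path = Path(tmp.name)
    try:
        with open(sam_path, "wb") as sam:
            subprocess.run(
                [require_bwa(), "mem", "-t", str(threads), str(fasta), str(fq1), str(fq2)],
                stdout=sam,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        pysam.sort("-o", str(out_bam), str(sam_path))
        pysam.index(str(out_bam))
    finally:
        sam_path.unlink(missing_ok=True)
    return out_bam
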