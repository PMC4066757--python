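"""End-to-end simulation benchmark: plant events, sequence, map, call, score.

Two study designs are provided:

* :func:`run_pooled_benchmark` — several independently mutated copies of
  one synthetic reference, each sequenced at low depth and pooled, so
  every planted event segregates at frequency ``1/n_pools`` (shared
  excisions at ``k/n_pools``).  This is the pooled-arm comparison design.
* :func:`run_frequency_sweep` — one mutated genome per designed
  frequency; variant and reference read pools are mixed at that
  frequency and called at a fixed apparent depth.

Both return pooled confusion counts, frequency-estimation errors and
junction-accuracy rates.  An external bwa executable performs the
mapping; everything else runs in-process.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tepool.absence_caller import call_absences
from tepool.config import RunConfig
from tepool.evaluator import (
    MatchResult,
    frequency_errors,
    match_absences,
    match_insertions,
    score_junctions,
)
from tepool.formats_io import TELibrary
from tepool.insertion_caller import call_insertions
from tepool.mapping import bwa_index, bwa_mem
from tepool.pool_simulator import (
    SimConfig,
    SimTruthRecord,
    make_synthetic_reference,
    mix_pools,
    mutate_genome,
    simulate_reads,
    write_fasta,
)

logger = logging.getLogger(__name__)

CONTIG = "chrS"

# Synthetic family lengths span the range of real TE consensus lengths
# (a few hundred bp for short non-LTR fragments up to >10 kb for long
# LTR/telomeric retroelements).  Absence of the longest family is
# undetectable by construction: its locus span exceeds the mapping-
# artifact cap on pair spans, as for real long elements.  With eleven
# families and round-robin placement of 20 copies, that family
# contributes a single annotated copy (~5% of copies), matching the few
# per cent of real annotated elements whose span defeats the cap.
FAMILY_LENGTHS = (611, 1100, 1828, 2121, 2907, 4726, 5143, 5886, 7469, 9092, 11123)


def default_library(seed: int = 9001) -> TELibrary:
    """Eleven synthetic consensus sequences with realistic length spread."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    fams = {
        f"synTE{i + 1:02d}": bases[rng.integers(0, 4, n)].tobytes().decode()
        for i, n in enumerate(FAMILY_LENGTHS)
    }
    return TELibrary(fams)


@dataclass
class BenchmarkResult:
    """Pooled scores over one or more simulated datasets."""

    insertions: MatchResult = field(default_factory=MatchResult)
    absences: MatchResult = field(default_factory=MatchResult)

    def merge(self, ins: MatchResult, abs_: MatchResult) -> None:
        self.insertions.tp += ins.tp
        self.insertions.fp += ins.fp
        self.insertions.fn += ins.fn
        self.absences.tp += abs_.tp
        self.absences.fp += abs_.fp
        self.absences.fn += abs_.fn

    # aggregate metrics, on the natural 0-1 scale
    @property
    def insertion_freq_error(self) -> float:
        errs = frequency_errors(self.insertions)
        return float(np.mean(errs)) if errs else float("nan")

    @property
    def absence_freq_error(self) -> float:
        errs = frequency_errors(self.absences)
        return float(np.mean(errs)) if errs else float("nan")

    def junction_rates(self) -> tuple[float, float]:
        """(found, correct) over insertion and absence TPs combined."""
        combined = MatchResult(
            tp=self.insertions.tp + self.absences.tp, fp=[], fn=[]
        )
        return score_junctions(combined)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _call_both(
    bam: Path,
    library: TELibrary,
    annotation,
    reference: str,
    sim: SimConfig,
    min_reads: int = 1,
):
    cfg_ins = RunConfig(insert_mean=sim.insert_mean, insert_sd=sim.insert_sd,
                        min_reads=min_reads)
    ins_events, _ = call_insertions(bam, library, cfg_ins)
    cfg_abs = RunConfig(insert_mean=sim.insert_mean, insert_sd=sim.insert_sd,
                        min_reads=min_reads)
    abs_events, _ = call_absences(
        bam, annotation, {CONTIG: reference}, cfg_abs
    )
    return ins_events, abs_events


def _merge_excision_truth(
    truths: list[list[SimTruthRecord]], n_pools: int
) -> list[SimTruthRecord]:
    """Pool per-genome truth sets: insertion frequency 1/n_pools; an
    excision shared by k genomes has frequency k/n_pools."""
    merged: list[SimTruthRecord] = []
    exc_count: dict[str, SimTruthRecord] = {}
    exc_n: dict[str, int] = {}
    for truth in truths:
        for t in truth:
            if t.kind == "insertion":
                merged.append(
                    SimTruthRecord(
                        t.kind, t.family, t.contig, t.junctions, t.strand,
                        frequency=1.0 / n_pools, tsd=t.tsd,
                    )
                )
            else:
                exc_count.setdefault(t.copy_id, t)
                exc_n[t.copy_id] = exc_n.get(t.copy_id, 0) + 1
    for copy_id, t in exc_count.items():
        merged.append(
            SimTruthRecord(
                t.kind, t.family, t.contig, t.junctions, t.strand,
                frequency=exc_n[copy_id] / n_pools, copy_id=copy_id,
            )
        )
    return merged


def run_pooled_dataset(
    workdir: Path,
    seed: int,
    library: TELibrary | None = None,
    genome_length: int = 2_000_000,
    n_copies: int = 20,
    n_pools: int = 5,
    depth_per_pool: float = 5.0,
    n_insertions: int = 10,
    n_excisions: int = 10,
    sim: SimConfig | None = None,
) -> tuple[MatchResult, MatchResult]:
    """One pooled dataset: ``n_pools`` independently mutated genomes at
    ``depth_per_pool`` each, pooled, mapped and called."""
    sim = sim or SimConfig(n_insertions=n_insertions, n_excisions=n_excisions)
    library = library or default_library()
    seeds = _spawn_seeds(seed, 2 + 2 * n_pools)
    reference, annotation = make_synthetic_reference(
        genome_length, library, n_copies, seeds[0]
    )
    ref_fa = workdir / "reference.fa"
    write_fasta(ref_fa, {CONTIG: reference})
    bwa_index(ref_fa)

    truths: list[list[SimTruthRecord]] = []
    fq1_parts, fq2_parts = [], []
    for g in range(n_pools):
        sample, truth = mutate_genome(
            reference, annotation, library, n_insertions, n_excisions,
            seed=seeds[1 + g],
        )
        truths.append(truth)
        fq1, fq2, _ = simulate_reads(
            sample, depth_per_pool, seed=seeds[1 + n_pools + g], config=sim,
            out_prefix=workdir / f"pool{g}", name_prefix=f"g{g}",
        )
        fq1_parts.append(fq1)
        fq2_parts.append(fq2)

    pooled1, pooled2 = workdir / "pooled_1.fq", workdir / "pooled_2.fq"
    for out, parts in ((pooled1, fq1_parts), (pooled2, fq2_parts)):
        with open(out, "w") as fh:
            for p in parts:
                fh.write(p.read_text())
                p.unlink()
    bam = bwa_mem(ref_fa, pooled1, pooled2, workdir / "pooled.bam")

    truth = _merge_excision_truth(truths, n_pools)
    ins_events, abs_events = _call_both(bam, library, annotation, reference, sim)
    return match_insertions(ins_events, truth), match_absences(abs_events, truth)


def run_pooled_benchmark(
    seed: int,
    n_datasets: int = 4,
    workdir: str | Path | None = None,
    **kwargs,
) -> BenchmarkResult:
    """Repeat :func:`run_pooled_dataset` and pool the scores."""
    result = BenchmarkResult()
    seeds = _spawn_seeds(seed, n_datasets)
    for i in range(n_datasets):
        with _workdir(workdir, f"pooled{i}") as wd:
            ins, abs_ = run_pooled_dataset(wd, seeds[i], **kwargs)
        logger.info(
            "dataset %d: ins sens %.3f prec %.3f; abs sens %.3f prec %.3f",
            i, ins.sensitivity, ins.precision, abs_.sensitivity, abs_.precision,
        )
        result.merge(ins, abs_)
    return result


def run_frequency_sweep(
    seed: int,
    depth: float = 20.0,
    frequencies: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    genome_length: int = 1_000_000,
    n_copies: int = 20,
    n_insertions: int = 10,
    n_excisions: int = 10,
    workdir: str | Path | None = None,
    library: TELibrary | None = None,
    sim: SimConfig | None = None,
) -> tuple[BenchmarkResult, dict[float, BenchmarkResult]]:
    """Mix variant and reference pools at each designed frequency, call
    at fixed depth, and score.  Returns the pooled result and the
    per-frequency breakdown."""
    sim = sim or SimConfig(n_insertions=n_insertions, n_excisions=n_excisions)
    library = library or default_library()
    seeds = _spawn_seeds(seed, 1 + 4 * len(frequencies))
    pooled = BenchmarkResult()
    per_freq: dict[float, BenchmarkResult] = {}

    with _workdir(workdir, "sweep") as wd:
        reference, annotation = make_synthetic_reference(
            genome_length, library, n_copies, seeds[0]
        )
        ref_fa = wd / "reference.fa"
        write_fasta(ref_fa, {CONTIG: reference})
        bwa_index(ref_fa)
        for i, freq in enumerate(frequencies):
            s = seeds[1 + 4 * i : 1 + 4 * (i + 1)]
            sample, truth = mutate_genome(
                reference, annotation, library, n_insertions, n_excisions, seed=s[0]
            )
            truth = [
                SimTruthRecord(
                    t.kind, t.family, t.contig, t.junctions, t.strand,
                    frequency=freq, copy_id=t.copy_id, tsd=t.tsd,
                )
                for t in truth
            ]
            simulate_reads(sample, depth, seed=s[1], config=sim,
                           out_prefix=wd / "variant", name_prefix="v")
            if freq < 1.0:
                simulate_reads(reference, depth, seed=s[2], config=sim,
                               out_prefix=wd / "refpool", name_prefix="r")
                fq1, fq2, _ = mix_pools(wd / "variant", wd / "refpool", freq,
                                        s[3], wd / "mixed")
            else:
                fq1, fq2 = wd / "variant_1.fq", wd / "variant_2.fq"
            bam = bwa_mem(ref_fa, fq1, fq2, wd / "mixed.bam")
            ins_events, abs_events = _call_both(
                bam, library, annotation, reference, sim
            )
            res = BenchmarkResult()
            res.merge(
                match_insertions(ins_events, truth),
                match_absences(abs_events, truth),
            )
            per_freq[freq] = res
            pooled.merge(res.insertions, res.absences)
    return pooled, per_freq


def detection_rate(
    per_freq: dict[float, BenchmarkResult], min_frequency: float = 0.3
) -> float:
    """Combined presence+absence recall over designed frequencies at or
    above ``min_frequency``."""
    tp = fn = 0
    for f, res in per_freq.items():
        if f >= min_frequency - 1e-9:
            tp += len(res.insertions.tp) + len(res.absences.tp)
            fn += len(res.insertions.fn) + len(res.absences.fn)
    return tp / (tp + fn) if tp + fn else float("nan")


class _workdir:
    """Use the given directory or a self-cleaning temporary one."""

    def __init__(self, base: str | Path | None, name: str):
        self.base = base
        self.name = name
        self._tmp = None

    def __enter__(self) -> Path:
        if self.base is None:
            self._tmp = tempfile.TemporaryDirectory(prefix=f"tepool_{self.name}_")
            return Path(self._tmp.name)
        d = Path(self.base) / self.name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def __exit__(self, *exc) -> None:
        if self._tmp is not None:
            self._tmp.cleanup()
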