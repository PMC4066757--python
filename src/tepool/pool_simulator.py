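"""Synthetic genomes, planted TE events, paired-end reads and pool mixing.

The generator emulates the data a pooled TE-polymorphism study produces:

* a reference genome of uniform random sequence carrying annotated TE
  copies.  Planted copies are *diverged* from their family consensus
  (default 25% substitutions), emulating old fixed insertions, while
  newly planted insertions use the exact consensus, emulating a young,
  active element.  This reproduces the regime the caller relies on: reads
  from a new insertion have no good placement on the reference, whereas
  reads from annotated copies map uniquely.
* sample genomes derived from the reference by planting full-length
  consensus insertions (optionally with a designed target-site
  duplication) and excising whole annotated copies;
* paired-end reads with normally distributed insert sizes (truncated at
  twice the read length), FR orientation, uniform substitution errors and
  constant base qualities;
* pooled read sets mixing variant and reference pools at a designed
  event frequency.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tepool.formats_io import (
    GenomicInterval,
    TEAnnotation,
    TEAnnotationSet,
    TELibrary,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_RC = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _RC[arr[::-1]]


@dataclass
class SimConfig:
    """Defaults of the simulation study: 90 nt reads, 500 +/- 50 bp
    fragments, substitution rate 1e-4, no indels, no GC bias."""

    read_length: int = 90
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 1e-4
    n_insertions: int = 50
    n_excisions: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length >= self.insert_mean:
            raise ValueError("read length must be below the mean insert size")


@dataclass(frozen=True)
class SimTruthRecord:
    """One planted event with its exact reference-frame junction(s)."""

    kind: str  # {"insertion", "excision"}
    family: str
    contig: str
    junctions: tuple[int, ...]  # insertion: (site,); excision: (start, end)
    strand: str
    frequency: float | None = None  # designed pool frequency
    copy_id: str | None = None  # excised annotated copy
    tsd: int = 0

    @property
    def junction(self) -> int:
        return self.junctions[0]


def _mutate(arr: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    k = int(round(len(arr) * divergence))
    if k:
        pos = rng.choice(len(arr), size=k, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
    return out


def make_synthetic_reference(
    length: int,
    library: TELibrary,
    n_copies: int,
    seed: int,
    divergence: float = 0.25,
    min_gap: int = 1000,
    contig: str = "chrS",
    max_tries: int = 1000,
) -> tuple[str, TEAnnotationSet]:
    """Uniform random genome with ``n_copies`` full-length TE copies
    planted at non-overlapping sites (round-robin over families, random
    strand), each diverged from its consensus by ``divergence``
    substitutions.  Returns the sequence and its annotation."""
    if length < 100_000:
        raise ValueError("reference length must be at least 100 kb")
    rng = np.random.default_rng(seed)
    genome = rng.integers(0, 4, size=length, dtype=np.uint8)
    families = sorted(library.families)
    placed: list[tuple[int, int]] = []
    copies: list[TEAnnotation] = []
    counters: dict[str, int] = {}
    for i in range(n_copies):
        family = families[i % len(families)]
        cons = encode(library[family])
        L = len(cons)
        for _ in range(max_tries):
            start = int(rng.integers(min_gap, length - L - min_gap))
            if all(
                start - min_gap >= e or start + L + min_gap <= s
                for s, e in placed
            ):
                break
        else:
            raise RuntimeError("could not place TE copies without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        copy_seq = _mutate(cons, divergence, rng)
        if strand == "-":
            copy_seq = _revcomp(copy_seq)
        genome[start : start + L] = copy_seq
        placed.append((start, start + L))
        counters[family] = counters.get(family, 0) + 1
        copies.append(
            TEAnnotation(
                f"{family}#{counters[family]}",
                family,
                GenomicInterval(contig, start, start + L, strand),
            )
        )
    return decode(genome), TEAnnotationSet(copies)


def mutate_genome(
    reference: str,
    annotation: TEAnnotationSet,
    library: TELibrary,
    n_insertions: int,
    n_excisions: int,
    seed: int,
    tsd_length: int = 0,
    margin: int = 1000,
    contig: str = "chrS",
    max_tries: int = 1000,
) -> tuple[str, list[SimTruthRecord]]:
    """Plant ``n_insertions`` full-consensus insertions (random family,
    strand and site, optional designed TSD) and excise ``n_excisions``
    annotated copies chosen without replacement.  Truth junctions are in
    reference coordinates."""
    if n_excisions > len(annotation):
        raise ValueError("more excisions requested than annotated copies")
    rng = np.random.default_rng(seed)
    families = sorted(library.families)

    all_copies = sorted(annotation, key=lambda c: c.copy_id)
    excised = sorted(
        (all_copies[i] for i in rng.choice(len(all_copies), n_excisions, replace=False)),
        key=lambda c: c.interval.start,
    )
    blocked = [(c.interval.start, c.interval.end) for c in excised]

    sites: list[tuple[int, str, str]] = []
    for _ in range(n_insertions):
        family = families[int(rng.integers(len(families)))]
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(max_tries):
            site = int(rng.integers(margin, len(reference) - margin))
            if all(site <= s or site >= e for s, e in blocked) and all(
                abs(site - s) > 2 * tsd_length + 1 for s, _, _ in sites
            ):
                break
        else:
            raise RuntimeError("could not place insertions")
        sites.append((site, family, strand))

    truth: list[SimTruthRecord] = []
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement)
    for site, family, strand in sites:
        cons = library[family]
        if strand == "-":
            cons = decode(_revcomp(encode(cons)))
        # a TSD duplicates the tsd_length bases immediately upstream
        insert_seq = cons + reference[site - tsd_length : site]
        edits.append((site, site, insert_seq))
        truth.append(
            SimTruthRecord(
                "insertion", family, contig, (site,), strand, tsd=tsd_length
            )
        )
    for c in excised:
        edits.append((c.interval.start, c.interval.end, ""))
        truth.append(
            SimTruthRecord(
                "excision",
                c.family,
                contig,
                (c.interval.start, c.interval.end),
                c.interval.strand,
                copy_id=c.copy_id,
            )
        )

    sample = []
    pos = 0
    for start, end, repl in sorted(edits):
        sample.append(reference[pos:start])
        sample.append(repl)
        pos = end
    sample.append(reference[pos:])
    truth.sort(key=lambda t: (t.junctions[0], t.kind, t.family))
    return "".join(sample), truth


def simulate_reads(
    genome: str,
    depth: float,
    seed: int,
    config: SimConfig | None = None,
    out_prefix: str | Path = "reads",
    name_prefix: str = "sim",
) -> tuple[Path, Path, int]:
    """Paired-end reads at the requested haploid depth, written as
    ``<out_prefix>_1.fq`` / ``_2.fq``.  Fragment positions are uniform,
    insert sizes Normal(mean, sd) truncated at twice the read length,
    mate orientation FR, substitution errors uniform over the three
    alternative bases, base qualities constant 'I'."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    g = encode(genome)
    G = len(g)
    rl = cfg.read_length
    n = int(round(depth * G / (2 * rl)))
    frag = np.maximum(
        np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)).astype(np.int64),
        2 * rl,
    )
    frag = np.minimum(frag, G)
    start = (rng.random(n) * (G - frag + 1)).astype(np.int64)

    idx1 = start[:, None] + np.arange(rl)
    idx2 = (start + frag)[:, None] + np.arange(-rl, 0)
    r1 = g[idx1]
    r2 = _RC[g[idx2][:, ::-1]]
    if cfg.error_rate > 0:
        for r in (r1, r2):
            m = rng.random(r.shape) < cfg.error_rate
            nerr = int(m.sum())
            if nerr:
                r[m] = (r[m] + rng.integers(1, 4, size=nerr).astype(np.uint8)) % 4

    out_prefix = Path(out_prefix)
    paths = (
        out_prefix.parent / f"{out_prefix.name}_1.fq",
        out_prefix.parent / f"{out_prefix.name}_2.fq",
    )
    qual = "I" * rl
    for mate, (path, reads) in enumerate(zip(paths, (r1, r2)), start=1):
        with open(path, "w") as fh:
            chunks = []
            for j in range(n):
                chunks.append(
                    f"@{name_prefix}:{j}/{mate}\n{decode(reads[j])}\n+\n{qual}\n"
                )
                if len(chunks) >= 20000:
                    fh.write("".join(chunks))
                    chunks = []
            fh.write("".join(chunks))
    return paths[0], paths[1], n


def _iter_fastq_pairs(fq1: Path, fq2: Path):
    import pysam

    with pysam.FastxFile(str(fq1)) as h1, pysam.FastxFile(str(fq2)) as h2:
        for a, b in zip(h1, h2):
            yield a, b


def mix_pools(
    variant_prefix: str | Path,
    reference_prefix: str | Path,
    frequency: float,
    seed: int,
    out_prefix: str | Path,
) -> tuple[Path, Path, int]:
    """Mix variant and reference read pools at a designed event frequency.

    The output has as many pairs as the variant pool; each slot draws a
    variant pair with probability ``frequency`` (binomial pool sizes),
    sampling without replacement within each pool.  ``frequency=1``
    returns the variant pool unchanged.
    """
    if not 0 < frequency <= 1:
        raise ValueError("frequency must be in (0, 1]")
    variant_prefix, reference_prefix = Path(variant_prefix), Path(reference_prefix)
    out_prefix = Path(out_prefix)
    v1, v2 = (variant_prefix.parent / f"{variant_prefix.name}_{i}.fq" for i in (1, 2))
    r1, r2 = (reference_prefix.parent / f"{reference_prefix.name}_{i}.fq" for i in (1, 2))
    o1 = out_prefix.parent / f"{out_prefix.name}_1.fq"
    o2 = out_prefix.parent / f"{out_prefix.name}_2.fq"

    rng = np.random.default_rng(seed)
    n_var = sum(1 for _ in pysam_fastx_count(v1))
    n_ref = sum(1 for _ in pysam_fastx_count(r1))
    k_var = int(rng.binomial(n_var, frequency))
    k_ref = n_var - k_var
    if k_ref > n_ref:
        raise ValueError("reference pool too small for requested mixture")
    take_var = np.zeros(n_var, dtype=bool)
    take_var[rng.choice(n_var, size=k_var, replace=False)] = True
    take_ref = np.zeros(n_ref, dtype=bool)
    take_ref[rng.choice(n_ref, size=k_ref, replace=False)] = True

    with open(o1, "w") as f1, open(o2, "w") as f2:
        for (fq1, fq2), mask in (((v1, v2), take_var), ((r1, r2), take_ref)):
            for i, (a, b) in enumerate(_iter_fastq_pairs(fq1, fq2)):
                if mask[i]:
                    f1.write(f"@{a.name}\n{a.sequence}\n+\n{a.quality}\n")
                    f2.write(f"@{b.name}\n{b.sequence}\n+\n{b.quality}\n")
    return o1, o2, n_var


def pysam_fastx_count(path: Path):
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        yield from fh


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: list[SimTruthRecord], path: str | Path) -> None:
    """Tab-delimited truth set with BED-compatible coordinates."""
    with open(path, "w") as fh:
        fh.write("kind\tfamily\tcontig\tjunctions\tstrand\tfrequency\tcopy_id\ttsd\n")
        for t in truth:
            fh.write(
                "\t".join(
                    [
                        t.kind,
                        t.family,
                        t.contig,
                        ",".join(map(str, t.junctions)),
                        t.strand,
                        "." if t.frequency is None else f"{t.frequency:.4f}",
                        t.copy_id or ".",
                        str(t.tsd),
                    ]
                )
                + "\n"
            )


def read_truth(path: str | Path) -> list[SimTruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                SimTruthRecord(
                    kind=f["kind"],
                    family=f["family"],
                    contig=f["contig"],
                    junctions=tuple(int(x) for x in f["junctions"].split(",")),
                    strand=f["strand"],
                    frequency=None if f["frequency"] == "." else float(f["frequency"]),
                    copy_id=None if f["copy_id"] == "." else f["copy_id"],
                    tsd=int(f["tsd"]),
                )
            )
    return out
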