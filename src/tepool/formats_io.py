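"""Domain types and readers/writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open ``[start, end)`` (BED
style).  A *junction* is the point between two reference bases and is
represented by the index of the base to its right: junction ``j`` lies
between ``ref[j-1]`` and ``ref[j]``.  Consequently an interval of bases
``[a, b)`` brackets the junction slots ``a..b`` inclusive.

RepeatMasker ``.out`` files use 1-based inclusive coordinates and are
converted on load; BED input is taken as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# core coordinate / read types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.contig, max(self.start, other.start), min(self.end, other.end)
        )

    def contains_junction(self, j: int) -> bool:
        """True if junction slot ``j`` falls inside this base interval."""
        return self.start <= j <= self.end


@dataclass(slots=True)
class AlignedRead:
    """One mate of a read pair, as needed by the callers.

    ``seq`` is the read sequence in reference-forward orientation (as
    stored in the BAM record); for reverse-strand alignments the original
    sequenced read is its reverse complement.  ``clip_left``/``clip_right``
    are soft-clip lengths at the reference-left / reference-right end of
    the alignment, with the clipped sequences alongside.
    """

    name: str
    contig: str | None
    start: int
    end: int
    strand: str
    mapq: int
    is_unique: bool
    is_mapped: bool
    is_read1: bool
    mate_contig: str | None
    mate_start: int
    mate_strand: str
    mate_mapped: bool
    clip_left: int
    clip_right: int
    clip_left_seq: str
    clip_right_seq: str
    seq: str

    @property
    def sequenced_seq(self) -> str:
        """The read as it came off the sequencer (undo reference-strand flip).

        Aligners store reverse-strand alignments — and also placed
        unmapped mates whose reverse flag is set — as the reverse
        complement of the sequenced read.
        """
        if self.strand == "-":
            return revcomp(self.seq)
        return self.seq


def aligned_read_from_pysam(
    rec: "pysam.AlignedSegment", mapq_unique: int = 20
) -> AlignedRead:
    mapped = not rec.is_unmapped
    clip_left = clip_right = 0
    cl_seq = cr_seq = ""
    seq = rec.query_sequence or ""
    if mapped and rec.cigartuples:
        first_op, first_len = rec.cigartuples[0]
        last_op, last_len = rec.cigartuples[-1]
        if first_op == 4:  # soft clip
            clip_left = first_len
            cl_seq = seq[:first_len]
        if last_op == 4:
            clip_right = last_len
            cr_seq = seq[len(seq) - last_len :]
    return AlignedRead(
        name=rec.query_name,
        contig=rec.reference_name if mapped else None,
        start=rec.reference_start if mapped else -1,
        end=rec.reference_end if mapped else -1,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        is_unique=mapped and rec.mapping_quality >= mapq_unique,
        is_mapped=mapped,
        is_read1=rec.is_read1,
        mate_contig=rec.next_reference_name if not rec.mate_is_unmapped else None,
        mate_start=rec.next_reference_start,
        mate_strand="-" if rec.mate_is_reverse else "+",
        mate_mapped=not rec.mate_is_unmapped,
        clip_left=clip_left,
        clip_right=clip_right,
        clip_left_seq=cl_seq,
        clip_right_seq=cr_seq,
        seq=seq,
    )


def read_alignments(
    path: str | Path,
    region: GenomicInterval | None = None,
    mapq_unique: int = 20,
) -> Iterator[AlignedRead]:
    """Yield primary alignments (and placed unmapped mates) from a BAM/SAM file.

    With ``region`` the BAM must be indexed; reads overlapping the region
    are returned.  Secondary and supplementary records are skipped.
    Malformed records are skipped with a logged warning.
    """
    path = str(path)
    skipped = 0
    with pysam.AlignmentFile(path) as bam:
        it = (
            bam.fetch(region.contig, region.start, region.end)
            if region is not None
            else bam.fetch(until_eof=True)
        )
        for rec in it:
            if rec.is_secondary or rec.is_supplementary:
                continue
            try:
                yield aligned_read_from_pysam(rec, mapq_unique=mapq_unique)
            except (ValueError, TypeError):  # pragma: no cover - defensive
                skipped += 1
    if skipped:
        logger.warning("skipped %d malformed records in %s", skipped, path)


def pair_up(reads: Iterable[AlignedRead]) -> Iterator[tuple[AlignedRead, AlignedRead]]:
    """Group an alignment stream into read pairs by query name."""
    pending: dict[str, AlignedRead] = {}
    for read in reads:
        other = pending.pop(read.name, None)
        if other is None:
            pending[read.name] = read
        elif other.is_read1 == read.is_read1:
            # duplicate record for the same mate; keep waiting for the other
            pending[read.name] = read
        else:
            yield (read, other) if read.is_read1 else (other, read)


# ---------------------------------------------------------------------------
# TE library and annotation
# ---------------------------------------------------------------------------


class TELibrary:
    """Mapping from TE family name to consensus sequence (uppercase A/C/G/T/N)."""

    def __init__(
        self,
        families: dict[str, str],
        superfamilies: dict[str, str] | None = None,
    ) -> None:
        if not families:
            raise ValueError("TE library must contain at least one family")
        for name, seq in families.items():
            if not seq:
                raise ValueError(f"empty consensus for family {name!r}")
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid characters {bad} in family {name!r}")
        self.families = {name: seq.upper() for name, seq in families.items()}
        self.superfamilies = superfamilies or {}
        self._match_cache: dict | None = None  # built lazily by te_matcher

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, name: str) -> bool:
        return name in self.families

    def __getitem__(self, name: str) -> str:
        return self.families[name]

    def items(self):
        return self.families.items()


def load_te_library(fasta_path: str | Path) -> TELibrary:
    """Load consensus sequences from FASTA; family = first header token."""
    families: dict[str, str] = {}
    with pysam.FastxFile(str(fasta_path)) as fh:
        for rec in fh:
            name = rec.name.split()[0]
            if name in families:
                raise ValueError(f"duplicate family name {name!r} in {fasta_path}")
            families[name] = (rec.sequence or "").upper()
    if not families:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return TELibrary(families)


@dataclass(frozen=True)
class TEAnnotation:
    """One annotated TE copy in the reference genome."""

    copy_id: str
    family: str
    interval: GenomicInterval


class TEAnnotationSet:
    """Collection of annotated reference TE copies with interval lookup."""

    def __init__(self, copies: Iterable[TEAnnotation]) -> None:
        self.copies: list[TEAnnotation] = list(copies)
        seen = set()
        for c in self.copies:
            if c.copy_id in seen:
                raise ValueError(f"duplicate copy id {c.copy_id!r}")
            seen.add(c.copy_id)
        self._by_id = {c.copy_id: c for c in self.copies}
        self._trees: dict[str, IntervalTree] = {}
        for c in self.copies:
            tree = self._trees.setdefault(c.interval.contig, IntervalTree())
            tree.addi(c.interval.start, c.interval.end, c)

    def __len__(self) -> int:
        return len(self.copies)

    def __iter__(self) -> Iterator[TEAnnotation]:
        return iter(self.copies)

    def __getitem__(self, copy_id: str) -> TEAnnotation:
        return self._by_id[copy_id]

    def __contains__(self, copy_id: str) -> bool:
        return copy_id in self._by_id

    def overlapping(self, contig: str, start: int, end: int) -> list[TEAnnotation]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda c: (c.interval.start, c.copy_id),
        )

    def contained_in(self, contig: str, start: int, end: int) -> list[TEAnnotation]:
        """Copies fully inside [start, end)."""
        return [
            c
            for c in self.overlapping(contig, start, end)
            if c.interval.start >= start and c.interval.end <= end
        ]


def load_te_annotation(path: str | Path, dialect: str = "bed") -> TEAnnotationSet:
    """Load a reference TE annotation.

    ``dialect='repeatmasker_out'`` parses RepeatMasker ``.out`` files
    (1-based inclusive genome coordinates, converted to half-open);
    ``dialect='bed'`` parses BED4+ (contig, start, end, family[, ...strand]).
    Copy identifiers are ``family#<line-ordinal>`` unless the BED name
    field already contains ``#``.
    """
    if dialect not in ("repeatmasker_out", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    copies: list[TEAnnotation] = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "repeatmasker_out":
                    fields = line.split()
                    if fields[0] in ("SW", "score") or line.lstrip().startswith("There"):
                        continue  # header lines
                    contig = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[6])
                    strand = "+" if fields[8] == "+" else "-"
                    family = fields[9]
                else:
                    fields = line.split("\t")
                    contig = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    family = fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                if "#" in family:
                    family, _, copy_id = family.partition("#")
                    copy_id = f"{family}#{copy_id}"
                else:
                    counters[family] = counters.get(family, 0) + 1
                    copy_id = f"{family}#{counters[family]}"
                copies.append(
                    TEAnnotation(
                        copy_id, family, GenomicInterval(contig, start, end, strand)
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line ({exc})") from exc
    return TEAnnotationSet(copies)


def write_annotation_bed(annotation: TEAnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(
            annotation, key=lambda c: (c.interval.contig, c.interval.start, c.copy_id)
        ):
            fh.write(
                f"{c.interval.contig}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.copy_id}\t0\t{c.interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass
class InsertionEvent:
    """Clustered evidence for a sample-specific TE insertion.

    ``junction_plus`` is the junction supported by reads aligned upstream
    of the insertion point (soft clip at the reference-right end of their
    alignment); ``junction_minus`` by reads aligned downstream (clip at
    the reference-left end).  With a target-site duplication of length L,
    ``junction_plus - junction_minus == L``.
    """

    contig: str
    family: str
    strand: str
    interval: GenomicInterval
    junction_plus: int | None = None
    junction_minus: int | None = None
    junction_resolution: str = "interval"  # {"base", "interval"}
    support_sides: str = "both"  # {"both", "left_only", "right_only"}
    T: int = 0
    R: int = 0
    frequency: float | None = None
    kind: str = "insertion"
    copy_ids: tuple[str, ...] = ()
    supports: list = field(default_factory=list, repr=False, compare=False)
    support_names: set = field(default_factory=set, repr=False, compare=False)

    @property
    def junction(self) -> int:
        """Best single junction estimate (used for reference-pair counting)."""
        if self.junction_resolution == "base":
            if self.junction_plus is not None:
                return self.junction_plus
            assert self.junction_minus is not None
            return self.junction_minus
        return (self.interval.start + self.interval.end) // 2

    def validate(self, clip_window: int = 20) -> None:
        if self.T < 1:
            raise ValueError("event must be supported by at least one pair")
        if self.frequency is not None and not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside (0, 1]")
        if self.junction_resolution == "base":
            if self.junction_plus is None and self.junction_minus is None:
                raise ValueError("base resolution without a junction estimate")
            lo = self.interval.start - clip_window
            hi = self.interval.end + clip_window
            for j in (self.junction_plus, self.junction_minus):
                if j is not None and not (lo <= j <= hi):
                    raise ValueError(
                        f"junction {j} outside extended interval [{lo}, {hi}]"
                    )


@dataclass
class AbsenceEvent:
    """Clustered evidence that reference-annotated TE copies are absent."""

    contig: str
    family: str
    strand: str
    interval: GenomicInterval  # span of the annotated copies
    copy_ids: tuple[str, ...]
    junction_plus: int | None = None  # refined left boundary
    junction_minus: int | None = None  # refined right boundary
    junction_resolution: str = "annotated"  # {"base", "annotated"}
    support_sides: str = "both"
    T: int = 0
    R: int = 0
    frequency: float | None = None
    kind: str = "absence"
    supports: list = field(default_factory=list, repr=False, compare=False)
    support_names: set = field(default_factory=set, repr=False, compare=False)

    @property
    def boundaries(self) -> tuple[int, int]:
        left = self.junction_plus if self.junction_plus is not None else self.interval.start
        right = self.junction_minus if self.junction_minus is not None else self.interval.end
        return left, right

    def validate(self, clip_window: int = 20) -> None:
        if self.T < 1:
            raise ValueError("event must be supported by at least one pair")
        if not self.copy_ids:
            raise ValueError("absence event must reference an annotated copy")
        if self.frequency is not None and not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside (0, 1]")


# ---------------------------------------------------------------------------
# event table I/O
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "contig",
    "start",
    "end",
    "family",
    "strand",
    "kind",
    "junction_plus",
    "junction_minus",
    "junction_resolution",
    "support_sides",
    "T",
    "R",
    "frequency",
    "copy_ids",
]


def _event_sort_key(ev) -> tuple:
    return (ev.contig, ev.interval.start, ev.family)


def write_events(
    events: Iterable[InsertionEvent | AbsenceEvent],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write a deterministic tab-delimited event summary (sorted by
    contig, start, family)."""
    rows = sorted(events, key=_event_sort_key)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for ev in rows:
            fh.write(
                "\t".join(
                    [
                        ev.contig,
                        str(ev.interval.start),
                        str(ev.interval.end),
                        ev.family,
                        ev.strand,
                        ev.kind,
                        "." if ev.junction_plus is None else str(ev.junction_plus),
                        "." if ev.junction_minus is None else str(ev.junction_minus),
                        ev.junction_resolution,
                        ev.support_sides,
                        str(ev.T),
                        str(ev.R),
                        f"{ev.frequency:.6f}" if ev.frequency is not None else ".",
                        ",".join(ev.copy_ids) if ev.copy_ids else ".",
                    ]
                )
                + "\n"
            )


def read_events(path: str | Path) -> list[InsertionEvent | AbsenceEvent]:
    """Parse a file written by :func:`write_events` (round-trip inverse)."""
    events: list[InsertionEvent | AbsenceEvent] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != EVENT_COLUMNS:
                    raise ValueError(f"unexpected header in {path}")
                continue
            f = dict(zip(header, line.split("\t")))
            common = dict(
                contig=f["contig"],
                family=f["family"],
                strand=f["strand"],
                interval=GenomicInterval(
                    f["contig"], int(f["start"]), int(f["end"]), f["strand"]
                ),
                junction_plus=None if f["junction_plus"] == "." else int(f["junction_plus"]),
                junction_minus=None if f["junction_minus"] == "." else int(f["junction_minus"]),
                junction_resolution=f["junction_resolution"],
                support_sides=f["support_sides"],
                T=int(f["T"]),
                R=int(f["R"]),
                frequency=None if f["frequency"] == "." else float(f["frequency"]),
            )
            copy_ids = () if f["copy_ids"] == "." else tuple(f["copy_ids"].split(","))
            if f["kind"] == "absence":
                events.append(AbsenceEvent(copy_ids=copy_ids, **common))
            else:
                events.append(InsertionEvent(copy_ids=copy_ids, **common))
    return events


def write_events_bed(
    events: Iterable[InsertionEvent | AbsenceEvent], path: str | Path
) -> None:
    """BED6 export for genome browsers: name=family, score=round(freq*1000)."""
    rows = sorted(events, key=_event_sort_key)
    with open(path, "w") as fh:
        for ev in rows:
            score = 0 if ev.frequency is None else round(ev.frequency * 1000)
            strand = ev.strand if ev.strand in "+-" else "."
            fh.write(
                f"{ev.contig}\t{ev.interval.start}\t{ev.interval.end}"
                f"\t{ev.family}\t{score}\t{strand}\n"
            )
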