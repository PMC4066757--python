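"""Refine event junctions to base-pair resolution from soft-clipped reads.

A soft-clipped alignment marks a candidate junction at the point where the
aligned segment stops.  Clips whose clipped portion is long enough
(>= ``min_clip``) and matches its expected source *perfectly* are
accepted: for insertions the source is the event's TE consensus (on the
strand implied by the insertion orientation); for absences it is the
genomic sequence on the far side of the deleted copy.

Junction estimates are side-specific.  ``junction_plus`` is the modal clip
point of reads aligned upstream of the junction (soft clip at the
reference-right end of the alignment); ``junction_minus`` comes from
downstream reads (clip at the reference-left end).  The signed difference
``junction_plus - junction_minus`` is the target-site duplication length
(negative values indicate target-site deletion).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from tepool.formats_io import (
    AbsenceEvent,
    AlignedRead,
    GenomicInterval,
    InsertionEvent,
    revcomp,
)

TRAILING = "trailing"  # clip at the reference-right end of the alignment
LEADING = "leading"  # clip at the reference-left end


@dataclass(frozen=True)
class ClipCandidate:
    """One soft-clip observation: the clip point and the clipped sequence."""

    name: str
    point: int  # junction slot where the aligned segment stops
    side: str  # TRAILING or LEADING
    seq: str  # clipped sequence, reference-forward orientation
    read_strand: str


def collect_clips(
    interval: GenomicInterval,
    reads: Iterable[AlignedRead],
    window: int = 20,
) -> list[ClipCandidate]:
    """Soft-clip candidates whose clip point lies within the interval
    widened by ``window`` bp on both sides (inclusive bounds; junction
    slots)."""
    lo, hi = interval.start - window, interval.end + window
    out: list[ClipCandidate] = []
    for r in reads:
        if not r.is_mapped:
            continue
        if r.clip_right and lo <= r.end <= hi:
            out.append(
                ClipCandidate(r.name, r.end, TRAILING, r.clip_right_seq, r.strand)
            )
        if r.clip_left and lo <= r.start <= hi:
            out.append(
                ClipCandidate(r.name, r.start, LEADING, r.clip_left_seq, r.strand)
            )
    return out


def validate_clip_insertion(
    clip: ClipCandidate,
    orientation: str,
    consensus: str,
    min_clip: int = 7,
) -> bool:
    """Accept a clip iff it is >= ``min_clip`` long and occurs verbatim in
    the event's consensus, oriented by the insertion strand.

    A perfect match anywhere in the consensus is accepted, which also
    covers junctions of internally truncated copies.
    """
    if len(clip.seq) < min_clip:
        return False
    target = consensus if orientation == "+" else revcomp(consensus)
    return clip.seq.upper() in target


def validate_clip_absence(
    clip: ClipCandidate,
    te_start: int,
    te_end: int,
    genome: str,
    min_clip: int = 7,
) -> bool:
    """Accept a clip near a deleted copy iff the clipped portion continues
    perfectly on the other side of the copy.

    A trailing clip at point q (near the left boundary ``te_start``) must
    equal the genome starting at ``te_end + (q - te_start)``; a leading
    clip at q near ``te_end`` must equal the genome ending at
    ``te_start + (q - te_end)``.
    """
    n = len(clip.seq)
    if n < min_clip:
        return False
    if clip.side == TRAILING:
        pos = te_end + (clip.point - te_start)
        if pos < 0 or pos + n > len(genome):
            return False
        return genome[pos : pos + n].upper() == clip.seq.upper()
    pos = te_start + (clip.point - te_end)
    if pos - n < 0 or pos > len(genome):
        return False
    return genome[pos - n : pos].upper() == clip.seq.upper()


def _modal_point(points: Sequence[int]) -> tuple[int, int] | None:
    """(position, count) with the most support; ties go to the smaller
    coordinate for determinism."""
    if not points:
        return None
    counts = Counter(points)
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return best


def refine_junction(
    event: InsertionEvent | AbsenceEvent,
    accepted_clips: Sequence[ClipCandidate],
) -> None:
    """Set per-side junction estimates on the event from accepted clips.

    With no accepted clip on either side, insertions fall back to the
    interval midpoint (resolution "interval") and absences to the
    annotated boundaries (resolution "annotated").
    """
    plus = _modal_point([c.point for c in accepted_clips if c.side == TRAILING])
    minus = _modal_point([c.point for c in accepted_clips if c.side == LEADING])
    if plus is None and minus is None:
        if isinstance(event, AbsenceEvent):
            event.junction_plus = event.interval.start
            event.junction_minus = event.interval.end
            event.junction_resolution = "annotated"
        else:
            event.junction_plus = None
            event.junction_minus = None
            event.junction_resolution = "interval"
        return
    event.junction_resolution = "base"
    if isinstance(event, AbsenceEvent):
        # keep annotated boundaries where one side lacks clip support
        event.junction_plus = plus[0] if plus else event.interval.start
        event.junction_minus = minus[0] if minus else event.interval.end
    else:
        event.junction_plus = plus[0] if plus else None
        event.junction_minus = minus[0] if minus else None


def tsd_length(junction_plus: int | None, junction_minus: int | None) -> int:
    """Signed target-site duplication length; negative = target-site
    deletion.  Both side-specific base estimates must be available."""
    if junction_plus is None or junction_minus is None:
        raise ValueError("TSD length requires base estimates on both sides")
    return junction_plus - junction_minus
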