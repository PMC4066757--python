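"""Detect reference-annotated TE copies that are absent from sample genomes.

A sample genome lacking an annotated copy yields read pairs whose mapped
distance on the reference is significantly longer than the library insert
(but below a cap that guards against mapping artifacts), and whose
distance becomes consistent with the insert size again once the spanned
TE copies are subtracted.  Both mates must map uniquely.  Pairs spanning
the same set of annotated copies are clustered into one event.

Spans are measured between the outer fragment ends (leftmost start to
rightmost end), the same convention as the library insert size; a copy
counts as spanned only when it lies fully between the two inner read
ends, since a partially overlapped copy cannot evidence absence of the
whole element.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from tepool.config import RunConfig
from tepool.formats_io import (
    AbsenceEvent,
    AlignedRead,
    GenomicInterval,
    TEAnnotation,
    TEAnnotationSet,
    pair_up,
    read_alignments,
)
from tepool.frequency_estimator import count_reference_absence, estimate_frequency
from tepool.insertion_caller import (
    _fetch_reads,
    estimate_insert_stats,
)
from tepool.junction_refiner import collect_clips, refine_junction, validate_clip_absence

logger = logging.getLogger(__name__)


@dataclass
class AbsenceSupport:
    """One long-span read pair consistent with absence of annotated copies."""

    pair: tuple[AlignedRead, AlignedRead]
    copies: tuple[TEAnnotation, ...]
    raw_span: int  # outer fragment span on the reference
    adjusted_span: int  # raw span minus the summed spanned-copy lengths

    @property
    def name(self) -> str:
        return self.pair[0].name


def extract_long_span(
    alignments: Iterable[AlignedRead],
    config: RunConfig,
    counters: Counter | None = None,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """FR pairs with both mates unique whose outer span exceeds
    ``insert_mean + span_z * insert_sd`` but stays below ``max_span``."""
    counters = counters if counters is not None else Counter()
    lo = config.insert_mean + config.span_z * config.insert_sd
    out: list[tuple[AlignedRead, AlignedRead]] = []
    for r1, r2 in pair_up(alignments):
        counters["pairs_scanned"] += 1
        if not (r1.is_mapped and r2.is_mapped and r1.is_unique and r2.is_unique):
            continue
        if r1.contig != r2.contig or r1.strand == r2.strand:
            continue
        fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
        if fwd.start > rev.start:
            continue
        span = rev.end - fwd.start
        if lo < span < config.max_span:
            out.append((fwd, rev))
            counters["long_span_pairs"] += 1
    return out


def check_te_span(
    candidate: tuple[AlignedRead, AlignedRead],
    annotation: TEAnnotationSet,
    config: RunConfig,
) -> AbsenceSupport | None:
    """Keep a long-span candidate iff at least one annotated copy lies
    fully between the inner read ends and the span minus the summed copy
    lengths is consistent with the library insert size."""
    fwd, rev = candidate
    inner_start, inner_end = fwd.end, rev.start
    if inner_start >= inner_end:
        return None
    copies = annotation.contained_in(fwd.contig, inner_start, inner_end)
    if not copies:
        return None
    raw = rev.end - fwd.start
    adjusted = raw - sum(len(c.interval) for c in copies)
    if abs(adjusted - config.insert_mean) > config.span_z * config.insert_sd:
        return None
    return AbsenceSupport(candidate, tuple(copies), raw, adjusted)


def cluster_absence(supports: Sequence[AbsenceSupport]) -> list[AbsenceEvent]:
    """One event per distinct set of spanned annotated copies."""
    groups: dict[tuple[str, ...], list[AbsenceSupport]] = {}
    for s in supports:
        key = tuple(c.copy_id for c in s.copies)
        groups.setdefault(key, []).append(s)
    events: list[AbsenceEvent] = []
    for key, members in sorted(groups.items()):
        copies = members[0].copies
        contig = copies[0].interval.contig
        start = min(c.interval.start for c in copies)
        end = max(c.interval.end for c in copies)
        families = sorted({c.family for c in copies})
        strands = {c.interval.strand for c in copies}
        events.append(
            AbsenceEvent(
                contig=contig,
                family=",".join(families),
                strand=strands.pop() if len(strands) == 1 else ".",
                interval=GenomicInterval(contig, start, end),
                copy_ids=key,
                junction_plus=start,
                junction_minus=end,
                T=len(members),
                supports=list(members),
                support_names={m.name for m in members},
            )
        )
    events.sort(key=lambda e: (e.contig, e.interval.start, e.family))
    return events


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def call_absences(
    bam_path: str | Path,
    annotation: TEAnnotationSet,
    genome: dict[str, str] | None = None,
    config: RunConfig | None = None,
) -> tuple[list[AbsenceEvent], Counter]:
    """Full absence pipeline on a coordinate-sorted, indexed BAM.

    ``genome`` maps contig name to sequence and enables base-resolution
    junction refinement from soft-clipped reads; without it events keep
    their annotated boundaries as junction estimates.
    """
    config = config or RunConfig()
    if config.insert_mean is None or config.insert_sd is None:
        mean, sd = estimate_insert_stats(bam_path, config.mapq_unique)
        config.insert_mean = config.insert_mean or mean
        config.insert_sd = config.insert_sd or max(sd, 1.0)
    counters: Counter = Counter()

    candidates = extract_long_span(
        read_alignments(bam_path, mapq_unique=config.mapq_unique), config, counters
    )
    supports = []
    for cand in candidates:
        sup = check_te_span(cand, annotation, config)
        if sup is not None:
            supports.append(sup)
    counters["absence_supports"] = len(supports)
    events = cluster_absence(supports)

    kept: list[AbsenceEvent] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for ev in events:
            _refine_and_quantify_absence(ev, bam, genome, config, counters)
            if ev.T >= config.min_reads and (
                ev.frequency is None or ev.frequency >= config.min_freq
            ):
                ev.validate(config.clip_window)
                kept.append(ev)
            else:
                counters["events_filtered"] += 1
    counters["events_reported"] = len(kept)
    return kept, counters


def _refine_and_quantify_absence(
    ev: AbsenceEvent,
    bam: pysam.AlignmentFile,
    genome: dict[str, str] | None,
    config: RunConfig,
    counters: Counter,
) -> None:
    s, e = ev.interval.start, ev.interval.end
    pad = config.clip_window + 200
    # clips cluster at the two annotated boundaries
    reads = _boundary_reads(bam, ev.contig, s, e, pad, config.mapq_unique)
    if genome is not None and ev.contig in genome:
        gseq = genome[ev.contig]
        candidates = [
            c
            for boundary in (s, e)
            for c in collect_clips(
                GenomicInterval(ev.contig, boundary, boundary + 1),
                reads,
                config.clip_window,
            )
        ]
        # a clip point near both boundaries (short copy) is validated once
        seen = set()
        accepted = []
        for c in candidates:
            key = (c.name, c.point, c.side)
            if key in seen:
                continue
            seen.add(key)
            if validate_clip_absence(c, s, e, gseq, config.min_clip):
                accepted.append(c)
        counters["clips_accepted"] += len(accepted)
        counters["clips_rejected"] += len(candidates) - len(accepted)
        refine_junction(ev, accepted)
        ev.support_names |= {c.name for c in accepted}
        ev.T = len(ev.support_names)
    radius = int(config.concordant_max_span) + 200
    left, right = ev.boundaries
    region = _boundary_reads(bam, ev.contig, left, right, radius, config.mapq_unique)
    ev.R = count_reference_absence(
        region, left, right, config, exclude_names=ev.support_names
    )
    ev.frequency = estimate_frequency(ev.T, ev.R)


def _boundary_reads(
    bam: pysam.AlignmentFile,
    contig: str,
    left: int,
    right: int,
    radius: int,
    mapq_unique: int,
) -> list[AlignedRead]:
    """Reads around two boundary points, de-duplicated when the windows
    overlap."""
    if right - left <= 2 * radius:
        return _fetch_reads(bam, contig, left - radius, right + radius, mapq_unique)
    reads = _fetch_reads(bam, contig, left - radius, left + radius, mapq_unique)
    reads += _fetch_reads(bam, contig, right - radius, right + radius, mapq_unique)
    seen = set()
    out = []
    for r in reads:
        key = (r.name, r.is_read1)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
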