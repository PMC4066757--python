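"""Detect sample-specific TE insertions from discordant read pairs.

A discordant pair has one uniquely mapped *anchor* read while its mate is
unmapped or non-uniquely mapped and matches a TE consensus.  The junction
must lie in the *interval estimate*: the stretch starting at the inner end
of the anchor and extending one mean insert size into the genome.
Supports of the same family and insertion orientation whose interval
estimates overlap by >= 1 bp are clustered; the intersection of the member
intervals is the refined interval estimate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from tepool.config import RunConfig
from tepool.formats_io import (
    AlignedRead,
    GenomicInterval,
    InsertionEvent,
    TELibrary,
    aligned_read_from_pysam,
    pair_up,
    read_alignments,
)
from tepool.frequency_estimator import count_reference_insertion, estimate_frequency
from tepool.junction_refiner import (
    collect_clips,
    refine_junction,
    validate_clip_insertion,
)
from tepool.te_matcher import MIN_READ_LEN, TEHit, best_te_hit

logger = logging.getLogger(__name__)


@dataclass
class DiscordantSupport:
    """One discordant pair supporting an insertion."""

    anchor: AlignedRead
    te_hit: TEHit
    interval: GenomicInterval
    orientation: str  # inferred insertion strand
    side: str  # "left": anchor upstream of the insertion; "right": downstream

    @property
    def family(self) -> str:
        return self.te_hit.family


def is_concordant(r1: AlignedRead, r2: AlignedRead, max_span: float) -> bool:
    """FR-oriented pair on one contig whose fragment span is within the
    library's concordance band (used to separate discordant evidence and
    to count reference pairs)."""
    if not (r1.is_mapped and r2.is_mapped) or r1.contig != r2.contig:
        return False
    if r1.strand == r2.strand:
        return False
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    if fwd.start > rev.start:
        return False
    return (rev.end - fwd.start) <= max_span


HOMOLOGY_SLACK = 5
ANCHOR_MIN_ALIGNED = 50


def interval_estimate(
    anchor: AlignedRead, insert_mean: float, contig_length: int | None = None
) -> GenomicInterval | None:
    """Interval guaranteed to contain the junction: from the inner end of
    the anchor, one mean insert size into the genome.

    The junction can sit exactly at the anchor's inner end (a junction is
    a slot *between* bases), so the half-open interval covers the
    ``insert_mean + 1`` candidate junction slots including that end.  The
    anchor-side end is additionally padded by ``HOMOLOGY_SLACK`` slots:
    when the first TE bases happen to equal the reference continuation
    (junction microhomology), the aligner extends a junction-adjacent
    anchor a few bases past the true junction, and the junction
    coordinate itself is ambiguous within the homology tract.  Returns
    ``None`` when clamping to the contig leaves an empty interval.
    """
    m = int(round(insert_mean))
    if anchor.strand == "+":
        start, end = anchor.end - HOMOLOGY_SLACK, anchor.end + m + 1
    else:
        start, end = anchor.start - m, anchor.start + 1 + HOMOLOGY_SLACK
    start = max(start, 0)
    if contig_length is not None:
        end = min(end, contig_length)
    if start >= end:
        logger.warning("degenerate clamped interval for anchor %s", anchor.name)
        return None
    return GenomicInterval(anchor.contig, start, end)


def infer_orientation(anchor_strand: str, te_hit_strand: str) -> str:
    """Insertion orientation from FR-library geometry.

    In an FR library the mate is sequenced on the opposite genomic strand
    of the anchor, so the insertion is forward ("+") exactly when the TE
    strand of the mate differs from the anchor strand:
    (+,+)->-, (+,-)->+, (-,+)->+, (-,-)->-.
    """
    return "+" if anchor_strand != te_hit_strand else "-"


def extract_discordant(
    alignments: Iterable[AlignedRead],
    library: TELibrary,
    config: RunConfig,
    contig_lengths: dict[str, int] | None = None,
    counters: Counter | None = None,
) -> list[DiscordantSupport]:
    """Scan paired alignments for discordant pairs whose non-anchor mate
    matches a TE consensus within the mismatch budget."""
    counters = counters if counters is not None else Counter()
    max_span = config.concordant_max_span
    supports: list[DiscordantSupport] = []
    for r1, r2 in pair_up(alignments):
        counters["pairs_scanned"] += 1
        if is_concordant(r1, r2, max_span):
            continue
        uniques = [r for r in (r1, r2) if r.is_mapped and r.is_unique]
        if len(uniques) != 1:
            continue
        anchor = uniques[0]
        mate = r2 if anchor is r1 else r1
        if mate.is_mapped and mate.is_unique:  # pragma: no cover
            continue
        # an anchor must localize the pair in genomic sequence: reject
        # fragmentary alignments (clipped on both ends, or only a short
        # segment aligned) that typically stem from element-internal
        # reads matching a stray conserved stretch of an annotated copy
        if (
            anchor.clip_left >= config.min_clip
            and anchor.clip_right >= config.min_clip
        ):
            counters["anchor_double_clipped"] += 1
            continue
        if anchor.end - anchor.start < ANCHOR_MIN_ALIGNED:
            counters["anchor_short_aligned"] += 1
            continue
        counters["discordant_pairs"] += 1
        mate_seq = mate.sequenced_seq
        if len(mate_seq) < MIN_READ_LEN:
            continue
        hit = best_te_hit(
            mate_seq, library, config.max_mismatch, config.n_is_wildcard
        )
        if hit is None:
            counters["te_unassigned_or_ambiguous"] += 1
            continue
        # the anchor must be genomic sequence: a read that itself matches
        # a consensus stems from inside an element (e.g. placed on a
        # diverged annotated copy) and cannot localize a new insertion
        if (
            len(anchor.sequenced_seq) >= MIN_READ_LEN
            and best_te_hit(
                anchor.sequenced_seq, library, config.max_mismatch,
                config.n_is_wildcard,
            )
            is not None
        ):
            counters["te_anchor_rejected"] += 1
            continue
        clen = (contig_lengths or {}).get(anchor.contig)
        interval = interval_estimate(anchor, config.insert_mean, clen)
        if interval is None:
            continue
        supports.append(
            DiscordantSupport(
                anchor=anchor,
                te_hit=hit,
                interval=interval,
                orientation=infer_orientation(anchor.strand, hit.strand),
                side="left" if anchor.strand == "+" else "right",
            )
        )
        counters["te_supports"] += 1
    return supports


def cluster_supports(supports: Sequence[DiscordantSupport]) -> list[InsertionEvent]:
    """Cluster supports of one family/orientation whose interval estimates
    overlap by >= 1 bp; the refined interval is the running intersection.

    Sorting by interval start makes the result independent of input order.
    Chains whose global intersection would be empty are split greedily
    left-to-right into maximal runs with a non-empty common intersection,
    so the refined interval is always an intersection of member intervals.
    """
    groups: dict[tuple[str, str, str], list[DiscordantSupport]] = {}
    for s in supports:
        groups.setdefault((s.interval.contig, s.family, s.orientation), []).append(s)

    events: list[InsertionEvent] = []
    for (contig, family, orientation), members in sorted(groups.items()):
        members.sort(key=lambda s: (s.interval.start, s.interval.end, s.anchor.name))
        current: list[DiscordantSupport] = []
        lo = hi = 0
        for s in members:
            if current and s.interval.start < hi:
                lo = max(lo, s.interval.start)
                hi = min(hi, s.interval.end)
                current.append(s)
            else:
                if current:
                    events.append(
                        _make_event(contig, family, orientation, current, lo, hi)
                    )
                current = [s]
                lo, hi = s.interval.start, s.interval.end
        if current:
            events.append(_make_event(contig, family, orientation, current, lo, hi))
    events.sort(key=lambda e: (e.contig, e.interval.start, e.family, e.strand))
    return events


def _make_event(
    contig: str,
    family: str,
    orientation: str,
    members: list[DiscordantSupport],
    lo: int,
    hi: int,
) -> InsertionEvent:
    sides = {m.side for m in members}
    support_sides = "both" if len(sides) == 2 else f"{sides.pop()}_only"
    ev = InsertionEvent(
        contig=contig,
        family=family,
        strand=orientation,
        interval=GenomicInterval(contig, lo, hi),
        support_sides=support_sides,
        T=len(members),
        supports=list(members),
        support_names={m.anchor.name for m in members},
    )
    return ev


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def estimate_insert_stats(
    bam_path: str | Path, mapq_unique: int = 20, max_pairs: int = 100_000
) -> tuple[float, float]:
    """Median fragment length and MAD-derived sd from concordant-looking
    pairs (templates between 0 and 100 kb, both mates mapped)."""
    spans = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if (
                rec.is_secondary
                or rec.is_supplementary
                or rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.mapping_quality < mapq_unique
            ):
                continue
            tlen = rec.template_length
            if 0 < tlen < 100_000:
                spans.append(tlen)
                if len(spans) >= max_pairs:
                    break
    if len(spans) < 100:
        raise ValueError(f"too few proper pairs in {bam_path} to estimate insert size")
    spans = np.asarray(spans, dtype=float)
    med = float(np.median(spans))
    sd = float(1.4826 * np.median(np.abs(spans - med)))
    return med, sd


def call_insertions(
    bam_path: str | Path,
    library: TELibrary,
    config: RunConfig | None = None,
) -> tuple[list[InsertionEvent], Counter]:
    """Full insertion pipeline on a coordinate-sorted, indexed BAM.

    Returns the filtered events plus a counter of pipeline statistics.
    """
    config = config or RunConfig()
    if config.insert_mean is None or config.insert_sd is None:
        mean, sd = estimate_insert_stats(bam_path, config.mapq_unique)
        config.insert_mean = config.insert_mean or mean
        config.insert_sd = config.insert_sd or max(sd, 1.0)
        logger.info("estimated insert size %.1f +/- %.1f", mean, sd)
    counters: Counter = Counter()

    with pysam.AlignmentFile(str(bam_path)) as bam:
        contig_lengths = dict(zip(bam.references, bam.lengths))

    supports = extract_discordant(
        read_alignments(bam_path, mapq_unique=config.mapq_unique),
        library,
        config,
        contig_lengths,
        counters,
    )
    events = cluster_supports(supports)

    kept: list[InsertionEvent] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for ev in events:
            _refine_and_quantify(ev, bam, library, config, counters)
            if ev.T >= config.min_reads and (
                ev.frequency is None or ev.frequency >= config.min_freq
            ):
                ev.validate(config.clip_window)
                kept.append(ev)
            else:
                counters["events_filtered"] += 1
    counters["events_reported"] = len(kept)
    return kept, counters


def _fetch_reads(
    bam: pysam.AlignmentFile, contig: str, start: int, end: int, mapq_unique: int
) -> list[AlignedRead]:
    clen = bam.get_reference_length(contig)
    out = []
    for rec in bam.fetch(contig, max(0, start), min(end, clen)):
        if rec.is_secondary or rec.is_supplementary:
            continue
        out.append(aligned_read_from_pysam(rec, mapq_unique=mapq_unique))
    return out


def _refine_and_quantify(
    ev: InsertionEvent,
    bam: pysam.AlignmentFile,
    library: TELibrary,
    config: RunConfig,
    counters: Counter,
) -> None:
    pad = config.clip_window + 200
    reads = _fetch_reads(
        bam, ev.contig, ev.interval.start - pad, ev.interval.end + pad,
        config.mapq_unique,
    )
    candidates = collect_clips(ev.interval, reads, config.clip_window)
    consensus = library[ev.family]
    accepted = [
        c
        for c in candidates
        if validate_clip_insertion(c, ev.strand, consensus, config.min_clip)
    ]
    counters["clips_accepted"] += len(accepted)
    counters["clips_rejected"] += len(candidates) - len(accepted)
    refine_junction(ev, accepted)

    ev.support_names |= {c.name for c in accepted}
    ev.T = len(ev.support_names)

    radius = int(config.concordant_max_span) + 200
    j = ev.junction
    jp = ev.junction_plus if ev.junction_plus is not None else j
    jm = ev.junction_minus if ev.junction_minus is not None else j
    region = _fetch_reads(
        bam, ev.contig, min(jp, jm) - radius, max(jp, jm) + radius,
        config.mapq_unique,
    )
    ev.R = count_reference_insertion(
        region, jp, jm, config, exclude_names=ev.support_names
    )
    ev.frequency = estimate_frequency(ev.T, ev.R)
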