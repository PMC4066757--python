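"""Population frequency of an event as T/(T+R).

T counts distinct read pairs supporting the event (discordant pairs plus
accepted soft-clip reads; a pair contributing both counts once).  R counts
concordant, both-unique pairs whose fragment spans an estimated junction
with at least ``ref_flank`` bp on each side — evidence for the reference
allele.

R is accounted per estimated junction so that the fragment-placement
opportunity for reference evidence matches the one for presence evidence
(the proportionality assumption behind T/(T+R)):

* an insertion has two sample-genome junctions (upstream and downstream
  of the element), and both feed T; a reference fragment spanning the
  site is reference-consistent at *both* estimated junctions, so R sums
  the per-junction counts;
* an absence event has a single novel junction in the sample (the
  deletion joint), while a reference-allele fragment can span only one
  of the two annotated boundaries (the element is longer than a
  fragment), so R averages the two per-boundary counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from tepool.config import RunConfig
from tepool.formats_io import AlignedRead, pair_up


def count_supporting(
    support_names: Iterable[str], clip_names: Iterable[str]
) -> int:
    """Distinct read pairs contributing discordant or clip evidence."""
    return len(set(support_names) | set(clip_names))


def estimate_frequency(T: int, R: float) -> float:
    """T/(T+R); requires at least one supporting pair."""
    if T < 1:
        raise ValueError("frequency undefined for events with no support")
    if R < 0:
        raise ValueError("negative reference count")
    return T / (T + R)


def _spanning_fragments(
    reads: Sequence[AlignedRead],
    config: RunConfig,
    exclude_names: set[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Fragment intervals of concordant, both-unique pairs."""
    from tepool.insertion_caller import is_concordant  # local: avoid cycle

    max_span = config.concordant_max_span
    out = []
    for r1, r2 in pair_up(reads):
        if exclude_names and r1.name in exclude_names:
            continue
        if not (r1.is_unique and r2.is_unique):
            continue
        if not is_concordant(r1, r2, max_span):
            continue
        out.append(
            (r1.name, min(r1.start, r2.start), max(r1.end, r2.end))
        )
    return out


def _count_spanning(
    fragments: Iterable[tuple[str, int, int]], junction: int, flank: int
) -> int:
    return sum(
        1 for _, s, e in fragments if s <= junction - flank and junction + flank <= e
    )


def count_reference_insertion(
    reads: Sequence[AlignedRead],
    junction_plus: int,
    junction_minus: int,
    config: RunConfig,
    exclude_names: set[str] | None = None,
) -> int:
    """R for an insertion: concordant both-unique pairs spanning an
    estimated junction with >= ``ref_flank`` bp on each side, summed
    over the two per-strand junction estimates (which coincide for an
    event resolved only to an interval midpoint)."""
    frags = _spanning_fragments(reads, config, exclude_names)
    return _count_spanning(frags, junction_plus, config.ref_flank) + _count_spanning(
        frags, junction_minus, config.ref_flank
    )


def count_reference_absence(
    reads: Sequence[AlignedRead],
    left_boundary: int,
    right_boundary: int,
    config: RunConfig,
    exclude_names: set[str] | None = None,
) -> int:
    """R for an absence event: per-boundary spanning-pair counts averaged
    over the two boundaries (rounded to nearest integer)."""
    frags = _spanning_fragments(reads, config, exclude_names)
    r_left = _count_spanning(frags, left_boundary, config.ref_flank)
    r_right = _count_spanning(frags, right_boundary, config.ref_flank)
    return int(round((r_left + r_right) / 2.0))
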