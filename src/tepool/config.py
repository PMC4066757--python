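"""Run-time configuration shared by the callers and the CLI."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Tunables of the calling pipeline.

    Attributes
    ----------
    insert_mean, insert_sd:
        Library fragment-length mean and standard deviation in bp (outer
        distance between mate 5' ends).  ``None`` means "estimate from the
        first 100,000 concordant pairs of the BAM" (median / 1.4826*MAD).
    span_z:
        A pair is concordant when its fragment span is at most
        ``insert_mean + span_z * insert_sd``; a pair is "significantly
        longer than the library insert" (absence evidence) when its span
        exceeds that bound.
    max_span:
        Upper fragment-span cap for absence evidence; longer spans are
        treated as mapping artifacts and discarded.
    max_mismatch:
        Mismatch budget when assigning a candidate mate to a TE consensus.
    mapq_unique:
        Minimum mapping quality for a read to count as uniquely mapped.
    clip_window:
        Interval estimates are widened by this many bp on both sides
        before soft-clipped reads are collected.
    min_clip:
        Minimum length of a soft-clipped segment for junction evidence;
        the clipped sequence must match its expected source perfectly.
    ref_flank:
        A reference (R) pair must span the junction with at least this
        many bp of fragment on each side.
    min_reads:
        Report only events supported by at least this many read pairs.
    min_freq:
        Report only events with estimated frequency at least this value.
    """

    insert_mean: float | None = None
    insert_sd: float | None = None
    span_z: float = 3.0
    max_span: int = 10_000
    max_mismatch: int = 3
    mapq_unique: int = 20
    clip_window: int = 20
    min_clip: int = 7
    ref_flank: int = 7
    min_reads: int = 1
    min_freq: float = 0.0
    n_is_wildcard: bool = True
    seed: int = 0

    @property
    def concordant_max_span(self) -> float:
        if self.insert_mean is None or self.insert_sd is None:
            raise ValueError("insert size statistics are not set")
        return self.insert_mean + self.span_z * self.insert_sd

    def header_lines(self) -> list[str]:
        """Render the effective configuration as '#key=value' comment lines."""
        return [
            f"#{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
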