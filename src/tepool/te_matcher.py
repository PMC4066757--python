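"""Assign candidate reads to the TE consensus family they match with fewest mismatches.

Matching is ungapped and end-to-end: the read is slid over both strands of
every consensus and the placement with the globally fewest substitutions
wins, provided it stays within the mismatch budget.  Ties *between
families* at the minimal mismatch count are ambiguous and yield no hit.
``N`` (in read or consensus) matches anything when ``n_is_wildcard``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tepool.formats_io import TELibrary, revcomp

MIN_READ_LEN = 20

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class TEHit:
    """Best placement of a read on a TE consensus."""

    family: str
    strand: str  # consensus strand the read matches
    mismatches: int
    offset: int  # 0-based offset of the placement on the forward consensus


def _library_cache(library: TELibrary) -> dict:
    cache = library._match_cache
    if cache is None:
        cache = {}
        for family, seq in library.items():
            cache[family] = {
                "+": (seq, _encode(seq)),
                "-": (revcomp(seq), _encode(revcomp(seq))),
            }
        library._match_cache = cache
    return cache


def _mismatch_profile(
    cons: np.ndarray, read: np.ndarray, n_is_wildcard: bool
) -> np.ndarray:
    """Mismatch count of the read at every placement along the consensus."""
    windows = np.lib.stride_tricks.sliding_window_view(cons, len(read))
    neq = windows != read
    if n_is_wildcard:
        neq &= (windows != 4) & (read != 4)
    else:
        neq |= (windows == 4) | (read == 4)
    return neq.sum(axis=1)


def best_te_hit(
    read_seq: str,
    library: TELibrary,
    max_mismatch: int = 3,
    n_is_wildcard: bool = True,
) -> TEHit | None:
    """Return the fewest-mismatch ungapped placement of ``read_seq`` on the
    library, or ``None`` if no placement is within ``max_mismatch`` or the
    minimum is shared by more than one family (ambiguous).
    """
    if len(library) == 0:  # pragma: no cover - TELibrary forbids this
        raise ValueError("empty TE library")
    if len(read_seq) < MIN_READ_LEN:
        raise ValueError(
            f"read of length {len(read_seq)} below minimum {MIN_READ_LEN}"
        )
    read_seq = read_seq.upper()
    cache = _library_cache(library)

    # fast path: exact substring on either strand (the common case for
    # reads from an element identical to its consensus)
    exact: list[TEHit] = []
    for family, strands in cache.items():
        for strand in ("+", "-"):
            seq_str, _ = strands[strand]
            pos = seq_str.find(read_seq)
            if pos >= 0:
                offset = pos if strand == "+" else len(seq_str) - pos - len(read_seq)
                exact.append(TEHit(family, strand, 0, offset))
                break  # one strand hit is enough to flag the family
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        return None  # ambiguous between families
    if "N" in read_seq and n_is_wildcard:
        pass  # wildcard reads need the full scan even for 0 mismatches
    elif max_mismatch == 0:
        return None

    read = _encode(read_seq)
    best: TEHit | None = None
    best_mm = max_mismatch + 1
    tie = False
    for family, strands in cache.items():
        fam_best: TEHit | None = None
        fam_mm = -1
        for strand in ("+", "-"):
            _, cons = strands[strand]
            if len(cons) < len(read):
                continue
            profile = _mismatch_profile(cons, read, n_is_wildcard)
            i = int(np.argmin(profile))
            mm = int(profile[i])
            if fam_best is None or mm < fam_mm:
                offset = i if strand == "+" else len(cons) - i - len(read)
                fam_best = TEHit(family, strand, mm, offset)
                fam_mm = mm
        if fam_best is None or fam_mm > max_mismatch:
            continue
        if best is None or fam_mm < best_mm:
            best, best_mm, tie = fam_best, fam_mm, False
        elif fam_mm == best_mm:
            tie = True
    if best is None:
        return None
    if tie:
        return None  # ambiguous between families
    return best
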