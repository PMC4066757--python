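"""Cross-population analytics on called TE events.

* frequency change of a parental insertion between a progeny pool and the
  Mendelian expectation of the two parental pools, FC = F - (H + W) / 2;
* an exact one-generation Wright-Fisher null for how large a frequency
  change drift alone can produce in a finite population;
* mono-/dinucleotide composition of the sequence around insertion
  junctions versus flanking background, plus a junction-window FASTA for
  external motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from tepool.formats_io import InsertionEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyChange:
    """Deviation of the progeny frequency from the parental mean.

    F: frequency in the progeny pool; H, W: frequencies in the two
    parental pools.  ``fc`` is ``None`` for non-parental events (below
    the parental-frequency threshold in both parents).
    """

    F: float
    H: float
    W: float
    parental: bool
    fc: float | None


def frequency_change(
    F: float, H: float, W: float, parental_threshold: float = 0.10
) -> FrequencyChange:
    """FC = F - (H + W)/2 for events present in at least one parent above
    ``parental_threshold``; others are flagged non-parental."""
    for name, v in (("F", F), ("H", H), ("W", W)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    parental = max(H, W) > parental_threshold
    return FrequencyChange(F, H, W, parental, F - (H + W) / 2 if parental else None)


def wf_change_tail(n_chromosomes: int, delta: float) -> float:
    """Exact tail probability of a one-generation Wright-Fisher change.

    For X ~ Binomial(n, p) (n resampled chromosomes, parental frequency
    p), returns ``max_p P(|X/n - p| >= delta)`` over the frequency grid
    p in {0, 1/n, ..., 1}, by exact log-space summation.  This is the
    most permissive drift null: the largest probability, over any
    parental frequency, that drift alone moves the frequency by at least
    ``delta`` in one generation.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if not 0 <= delta < 1:
        raise ValueError("delta must be in [0, 1)")
    n = n_chromosomes
    k = np.arange(n + 1)
    best = -np.inf
    for i in range(n + 1):
        p = i / n
        logpmf = binom.logpmf(k, n, p)
        mask = np.abs(k / n - p) >= delta - 1e-12
        if mask.any():
            best = max(best, logsumexp(logpmf[mask]))
    return float(np.exp(best))


_KMERS = [a for a in "ACGT"] + [a + b for a in "ACGT" for b in "ACGT"]


def _kmer_counts(seqs: Sequence[str]) -> dict[str, int]:
    counts = {k: 0 for k in _KMERS}
    for s in seqs:
        s = s.upper()
        for i, c in enumerate(s):
            if c in "ACGT":
                counts[c] += 1
            if i + 1 < len(s):
                d = s[i : i + 2]
                if d in counts:
                    counts[d] += 1
    return counts


def junction_composition(
    events: Sequence[InsertionEvent],
    genome: dict[str, str],
    window: int = 15,
    background_flank: int = 100,
    fasta_out: str | Path | None = None,
) -> pd.DataFrame:
    """Mono- and dinucleotide enrichment around insertion junctions.

    For each event with base estimates on both sides, a window of
    ``2*window`` bp is centred on the midpoint between the two junctions;
    background windows of the same length are taken ``background_flank``
    bp upstream and downstream.  The enrichment ratio is the k-mer
    frequency in junction windows over its frequency in background
    windows.  Optionally writes the junction windows as FASTA (input for
    external motif tools).
    """
    windows: list[str] = []
    backgrounds: list[str] = []
    names: list[str] = []
    skipped = 0
    for ev in events:
        if (
            ev.junction_resolution != "base"
            or ev.junction_plus is None
            or ev.junction_minus is None
            or ev.contig not in genome
        ):
            skipped += 1
            continue
        seq = genome[ev.contig]
        mid = (ev.junction_plus + ev.junction_minus) // 2
        lo, hi = mid - window, mid + window
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        windows.append(seq[lo:hi])
        names.append(f"{ev.family}_{ev.contig}_{mid}")
        w = hi - lo
        up = seq[max(0, lo - background_flank - w) : max(0, lo - background_flank)]
        down = seq[hi + background_flank : hi + background_flank + w]
        backgrounds.extend(x for x in (up, down) if x)
    if skipped:
        logger.warning("%d events lacked two-sided base junctions; skipped", skipped)
    if fasta_out is not None and windows:
        with open(fasta_out, "w") as fh:
            for name, s in zip(names, windows):
                fh.write(f">{name}\n{s}\n")
    if not windows:
        logger.warning("no qualifying events for junction composition")
        return pd.DataFrame(
            columns=["kmer", "junction_count", "background_count", "ratio"]
        )
    jc = _kmer_counts(windows)
    bc = _kmer_counts(backgrounds)
    j_tot = {1: sum(v for k, v in jc.items() if len(k) == 1),
             2: sum(v for k, v in jc.items() if len(k) == 2)}
    b_tot = {1: sum(v for k, v in bc.items() if len(k) == 1),
             2: sum(v for k, v in bc.items() if len(k) == 2)}
    rows = []
    for k in _KMERS:
        jf = jc[k] / j_tot[len(k)] if j_tot[len(k)] else float("nan")
        bf = bc[k] / b_tot[len(k)] if b_tot[len(k)] else float("nan")
        rows.append(
            {
                "kmer": k,
                "junction_count": jc[k],
                "background_count": bc[k],
                "ratio": jf / bf if bf else float("inf"),
            }
        )
    return pd.DataFrame(rows)
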