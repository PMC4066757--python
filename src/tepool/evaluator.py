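"""Score predicted events against a simulation truth set.

Recovery criteria: a planted insertion is recovered when a predicted
insertion's interval estimate brackets the true junction *and* family and
orientation are correct; a planted excision is recovered when an absence
event references the corresponding annotated copy.  Each prediction
matches at most one truth record (greedy nearest-first); unmatched
predictions are false positives, unmatched truths false negatives.  A
junction is *found* when the event reached base resolution and *correct*
when a base estimate lies within 5 nt of a true junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tepool.formats_io import AbsenceEvent, InsertionEvent
from tepool.pool_simulator import SimTruthRecord

JUNCTION_TOLERANCE = 5


@dataclass
class MatchResult:
    tp: list[tuple[object, SimTruthRecord]] = field(default_factory=list)
    fp: list[object] = field(default_factory=list)
    fn: list[SimTruthRecord] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def sensitivity(self) -> float:
        denom = len(self.tp) + len(self.fn)
        return len(self.tp) / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = len(self.tp) + len(self.fp)
        return len(self.tp) / denom if denom else float("nan")

    @property
    def fdr(self) -> float:
        p = self.precision
        return float("nan") if np.isnan(p) else 1.0 - p


def _match_greedy(candidates: list[tuple[float, int, int]], n_pred: int, n_truth: int):
    """Greedy nearest-first one-to-one matching from (distance, pred_idx,
    truth_idx) candidates."""
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, pi, ti in sorted(candidates):
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        pairs.append((pi, ti))
    return pairs, used_p, used_t


def match_insertions(
    predictions: Sequence[InsertionEvent], truth: Sequence[SimTruthRecord]
) -> MatchResult:
    truth = [t for t in truth if t.kind == "insertion"]
    candidates = []
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predictions):
            if (
                p.contig == t.contig
                and p.family == t.family
                and p.strand == t.strand
                and p.interval.contains_junction(t.junction)
            ):
                center = (p.interval.start + p.interval.end) / 2
                candidates.append((abs(center - t.junction), pi, ti))
    pairs, used_p, used_t = _match_greedy(candidates, len(predictions), len(truth))
    res = MatchResult()
    res.tp = [(predictions[pi], truth[ti]) for pi, ti in pairs]
    res.fp = [p for i, p in enumerate(predictions) if i not in used_p]
    res.fn = [t for i, t in enumerate(truth) if i not in used_t]
    return res


def match_absences(
    predictions: Sequence[AbsenceEvent], truth: Sequence[SimTruthRecord]
) -> MatchResult:
    truth = [t for t in truth if t.kind == "excision"]
    candidates = []
    for ti, t in enumerate(truth):
        for pi, p in enumerate(predictions):
            if t.copy_id in p.copy_ids:
                candidates.append((float(len(p.copy_ids)), pi, ti))
    pairs, used_p, used_t = _match_greedy(candidates, len(predictions), len(truth))
    res = MatchResult()
    res.tp = [(predictions[pi], truth[ti]) for pi, ti in pairs]
    res.fp = [p for i, p in enumerate(predictions) if i not in used_p]
    res.fn = [t for i, t in enumerate(truth) if i not in used_t]
    return res


def frequency_errors(result: MatchResult) -> list[float]:
    """|estimated - designed| for matched pairs with both values known."""
    errs = []
    for p, t in result.tp:
        if p.frequency is not None and t.frequency is not None:
            errs.append(abs(p.frequency - t.frequency))
    return errs


def score_junctions(result: MatchResult) -> tuple[float, float]:
    """(junction-found rate over TPs, junction-correct rate over found).

    A base estimate is correct when it lies within ``JUNCTION_TOLERANCE``
    nt of a true junction on either side.
    """
    found = 0
    correct = 0
    for p, t in result.tp:
        if p.junction_resolution != "base":
            continue
        found += 1
        estimates = [j for j in (p.junction_plus, p.junction_minus) if j is not None]
        true_js = set(t.junctions)
        if t.kind == "insertion" and t.tsd:
            true_js.add(t.junction - t.tsd)  # downstream-strand junction
        if any(
            min(abs(e - j) for j in true_js) <= JUNCTION_TOLERANCE for e in estimates
        ):
            correct += 1
    n_tp = len(result.tp)
    return (
        found / n_tp if n_tp else float("nan"),
        correct / found if found else float("nan"),
    )


def metrics_row(
    result: MatchResult, kind: str, depth: float | None = None,
    frequency: float | None = None,
) -> dict:
    errs = frequency_errors(result)
    jfound, jcorrect = score_junctions(result)
    return {
        "kind": kind,
        "depth": depth,
        "frequency": frequency,
        "tp": len(result.tp),
        "fp": len(result.fp),
        "fn": len(result.fn),
        "sensitivity": result.sensitivity,
        "precision": result.precision,
        "fdr": result.fdr,
        "mean_abs_freq_error": float(np.mean(errs)) if errs else float("nan"),
        "junction_found": jfound,
        "junction_correct": jcorrect,
    }


def metrics_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-(depth, frequency, kind) rows into a deterministic table."""
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["kind", "depth", "frequency"], na_position="first"
    ).reset_index(drop=True)
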