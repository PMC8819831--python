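"""Evaluation statistics for cut-site labeling.

Because exactly one position is labeled per cut class, precision, recall and
F-score collapse into the same number; performance is therefore summarized
by the perfect match fraction (PMF), the fraction of examples whose
predicted position equals the annotation exactly, and the positional shift
error (PSE), the mean absolute offset in nucleotides:

    PMF = #{examples with the cut site correctly labeled} / #examples
    PSE = sum over examples |predicted - annotated| / #examples

Signed offsets are reported as predicted - annotated (positive = shifted
3'-ward).  Records lacking a given cut class (single-product precursors)
are excluded from that class's statistics rather than penalized.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import CUT_CLASSES

CutMap = Mapping[str, int]  # cut class -> position, for one record


def _check(pred: Sequence[int], true: Sequence[int]) -> np.ndarray:
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} truths")
    if len(pred) == 0:
        raise ValueError("at least one example is required")
    return np.asarray(pred, dtype=np.int64) - np.asarray(true, dtype=np.int64)


def pmf(pred_positions: Sequence[int], true_positions: Sequence[int]) -> float:
    """Perfect match fraction: exact-position agreement rate."""
    offsets = _check(pred_positions, true_positions)
    return float(np.mean(offsets == 0))


def pse(pred_positions: Sequence[int], true_positions: Sequence[int]) -> float:
    """Positional shift error: mean absolute offset in nucleotides."""
    offsets = _check(pred_positions, true_positions)
    return float(np.mean(np.abs(offsets)))


def within_distance(
    pred_positions: Sequence[int], true_positions: Sequence[int], d_max: int
) -> dict[int, float]:
    """Cumulative fraction of predictions with |offset| <= d, for d = 0..d_max."""
    offsets = np.abs(_check(pred_positions, true_positions))
    return {d: float(np.mean(offsets <= d)) for d in range(d_max + 1)}


def modal_offset(offsets_per_replicate: Sequence[int]) -> int:
    """Most frequent signed offset across replicates.

    Ties are broken toward the smaller absolute offset, then toward the
    negative (5'-ward) one.
    """
    if len(offsets_per_replicate) == 0:
        raise ValueError("at least one replicate offset is required")
    counts = Counter(int(o) for o in offsets_per_replicate)
    return min(counts, key=lambda o: (-counts[o], abs(o), o > 0))


@dataclass
class ClassReport:
    """Per-cut-class evaluation summary."""

    pmf: float
    pse: float
    offset_histogram: dict[int, int]
    within_d: dict[int, float]
    n_examples: int


@dataclass
class EvalReport:
    """Evaluation summary over the four cut classes."""

    classes: dict[str, ClassReport] = field(default_factory=dict)

    def __getitem__(self, cls: str) -> ClassReport:
        return self.classes[cls]

    def to_dict(self) -> dict:
        return {
            cls: {
                "pmf": r.pmf,
                "pse": r.pse,
                "offset_histogram": {str(k): v for k, v in r.offset_histogram.items()},
                "within_d": {str(k): v for k, v in r.within_d.items()},
                "n_examples": r.n_examples,
            }
            for cls, r in self.classes.items()
        }


def evaluate_predictions(
    preds: Mapping[str, CutMap],
    truths: Mapping[str, CutMap],
    d_max: int = 10,
) -> EvalReport:
    """Per-class PMF/PSE/offset statistics over records keyed by id.

    Only records present in both mappings and annotated for a class
    contribute to that class's report.
    """
    report = EvalReport()
    for cls in CUT_CLASSES:
        pairs = [
            (preds[rid][cls], true[cls])
            for rid, true in truths.items()
            if cls in true and rid in preds and cls in preds[rid]
        ]
        if not pairs:
            report.classes[cls] = ClassReport(np.nan, np.nan, {}, {}, 0)
            continue
        p, t = zip(*pairs)
        offsets = _check(p, t)
        hist = dict(sorted(Counter(int(o) for o in offsets).items()))
        report.classes[cls] = ClassReport(
            pmf=pmf(p, t),
            pse=pse(p, t),
            offset_histogram=hist,
            within_d=within_distance(p, t, d_max),
            n_examples=len(pairs),
        )
    return report


def stratified_eval(
    preds: Mapping[str, CutMap],
    truths: Mapping[str, CutMap],
    groups: Mapping[str, str],
    d_max: int = 10,
) -> dict[str, EvalReport]:
    """One report per subset label plus a ``"pooled"`` report over all records.

    ``groups`` maps record id to a subset label (e.g. mirtron vs canonical);
    every evaluated record must be grouped.  Empty subsets are omitted with
    a warning.
    """
    ungrouped = [rid for rid in truths if rid not in groups]
    if ungrouped:
        raise ValueError(f"records without a subset label: {ungrouped[:5]}")
    out: dict[str, EvalReport] = {}
    for label in sorted(set(groups.values())):
        sub = {rid: t for rid, t in truths.items() if groups[rid] == label}
        if not sub:
            warnings.warn(f"subset {label!r} is empty; omitted")
            continue
        out[label] = evaluate_predictions(preds, sub, d_max=d_max)
    out["pooled"] = evaluate_predictions(preds, truths, d_max=d_max)
    return out
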