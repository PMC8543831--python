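"""Residue-level and region-level evaluation metrics.

Residue level is the ordinary confusion matrix over hot/non-hot labels with

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F-measure = 2 * recall * precision / (recall + precision)
    accuracy  = (TP + TN) / total.

Region level compares predicted hot regions with standard hot regions under
the coverage rule: a standard region counts as correctly predicted when at
least 60% (by default) of its hot spots fall inside a single predicted
region, the boundary inclusive. Matching is one-to-one, greedy by descending
coverage fraction, so one predicted region cannot satisfy two standard
regions. TP is the number of matched pairs; unmatched standard regions are
FN, unmatched predicted regions FP; there is no region-level TN, so region
accuracy is not defined.

A metric whose denominator is zero is reported as None, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import HotRegion

DEFAULT_COVERAGE = 0.6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    recall: Optional[float]
    precision: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def f_measure(recall: Optional[float], precision: Optional[float]) -> Optional[float]:
    """Harmonic mean of recall and precision; None when undefined."""
    if recall is None or precision is None or (recall + precision) == 0:
        return None
    return 2 * recall * precision / (recall + precision)


def metrics_from_counts(counts: ConfusionCounts, with_accuracy: bool = True) -> MetricSet:
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    total = counts.tp + counts.fp + counts.fn + counts.tn
    accuracy = _ratio(counts.tp + counts.tn, total) if with_accuracy else None
    return MetricSet(recall, precision, f_measure(recall, precision), accuracy)


def residue_metrics(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[ConfusionCounts, MetricSet]:
    """Hot-spot-level confusion counts and metrics from aligned 0/1 labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must be aligned")
    counts = ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (truth == 1))),
        fp=int(np.sum((predicted == 1) & (truth == 0))),
        fn=int(np.sum((predicted == 0) & (truth == 1))),
        tn=int(np.sum((predicted == 0) & (truth == 0))),
    )
    return counts, metrics_from_counts(counts)


def f_measure_from_labels(predicted: np.ndarray, truth: np.ndarray) -> Optional[float]:
    """Convenience scorer for cross-validation loops."""
    return residue_metrics(predicted, truth)[1].f_measure


def coverage_fraction(predicted: HotRegion, standard: HotRegion) -> float:
    """Fraction of the standard region's hot spots inside the predicted region."""
    if len(standard) == 0:
        return 0.0
    return len(predicted.member_set & standard.member_set) / len(standard)


def match_regions(
    predicted: Sequence[HotRegion],
    standard: Sequence[HotRegion],
    coverage: float = DEFAULT_COVERAGE,
) -> ConfusionCounts:
    """One-to-one region matching under the coverage rule.

    Candidate pairs reaching the coverage threshold are sorted by descending
    coverage fraction (ties: larger predicted region, then lexicographic
    region ids) and matched greedily, each region participating at most once.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    candidates = []
    for s in standard:
        for p in predicted:
            if p.complex_id != s.complex_id:
                continue
            frac = coverage_fraction(p, s)
            if frac >= coverage:
                candidates.append((-frac, -len(p), p.region_id, s.region_id, p, s))
    candidates.sort(key=lambda c: c[:4])
    used_pred: set[str] = set()
    used_std: set[str] = set()
    tp = 0
    for _, _, pid, sid, _, _ in candidates:
        if pid in used_pred or sid in used_std:
            continue
        used_pred.add(pid)
        used_std.add(sid)
        tp += 1
    return ConfusionCounts(
        tp=tp, fp=len(predicted) - tp, fn=len(standard) - tp, tn=0
    )


def region_metrics(counts: ConfusionCounts) -> MetricSet:
    """Recall/precision/F over region counts; accuracy has no region meaning."""
    return metrics_from_counts(counts, with_accuracy=False)


def per_region_report(
    predicted: Sequence[HotRegion], standard: Sequence[HotRegion]
) -> pd.DataFrame:
    """Per standard region: its size and the best single-region overlap.

    The overlap column counts true hot spots of the standard region found in
    the predicted region that covers it best, mirroring the bar-chart style
    comparison of standard size vs true-positive hot spots.
    """
    rows = []
    for s in standard:
        overlaps = [
            len(p.member_set & s.member_set)
            for p in predicted
            if p.complex_id == s.complex_id
        ]
        rows.append(
            {
                "region_id": s.region_id,
                "n_hot_spots": len(s),
                "n_true_positive": max(overlaps, default=0),
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "n_hot_spots", "n_true_positive"])
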