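"""Max-relevance / min-redundancy feature ranking with incremental selection.

Mutual information between columns is estimated by the plug-in estimator on a
discretized joint: continuous columns are cut into equal-frequency bins
(default 10), discrete columns are used as-is, and MI is reported in nats.
Relevance of a feature set F against the label c is the mean MI(Xi, c) over F;
redundancy is the mean pairwise MI over all ordered pairs of F including the
diagonal (a literal reading of the 1/|F|^2 normalization; a switch excludes
the diagonal). The greedy ranking uses the difference (MID) criterion: the
next feature maximizes I(X, c) minus its mean MI with the already-selected
set. Ties break lexicographically by feature name so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_BINS = 10


@dataclass(frozen=True)
class MIEstimate:
    value: float  # nats
    bin_count: int
    sample_size: int


@dataclass
class FeatureRanking:
    """Features in descending greedy mRMR order with per-step scores."""

    features: list[str]
    scores: list[float]


def discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning for continuous data; small discrete supports pass through.

    A column whose number of distinct values does not exceed ``bins`` is
    treated as already discrete (integer codes by sorted value); otherwise
    quantile cut with duplicate bin edges merged.
    """
    x = np.asarray(x)
    uniq = np.unique(x)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, x)
    codes = pd.qcut(x, q=bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def _discrete_mi(xc: np.ndarray, yc: np.ndarray) -> float:
    joint = pd.crosstab(pd.Series(xc), pd.Series(yc)).to_numpy().astype(float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS
) -> MIEstimate:
    """Plug-in mutual information I(x, y) in nats after discretization."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    xc = discretize(x, bins)
    yc = discretize(y, bins)
    value = _discrete_mi(xc, yc)
    return MIEstimate(value=max(value, 0.0), bin_count=bins, sample_size=len(x))


def relevance(
    features: pd.DataFrame, labels: np.ndarray, bins: int = DEFAULT_BINS
) -> float:
    """Mean MI between each feature column and the label, in nats."""
    if features.shape[1] == 0:
        raise ValueError("relevance of an empty feature set is undefined")
    return float(
        np.mean(
            [
                mutual_information(features[c].to_numpy(), labels, bins).value
                for c in features.columns
            ]
        )
    )


def redundancy(
    features: pd.DataFrame, bins: int = DEFAULT_BINS, include_diagonal: bool = True
) -> float:
    """Mean pairwise MI over ordered feature pairs, normalized by |F|^2.

    ``include_diagonal`` keeps the i=j terms (each contributing the feature's
    own entropy); excluding them divides the off-diagonal sum by |F|^2 still.
    """
    p = features.shape[1]
    if p == 0:
        raise ValueError("redundancy of an empty feature set is undefined")
    cols = [features[c].to_numpy() for c in features.columns]
    total = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                if include_diagonal:
                    total += mutual_information(cols[i], cols[i], bins).value
            elif i < j:
                mi = mutual_information(cols[i], cols[j], bins).value
                total += 2 * mi  # symmetric, count (i,j) and (j,i)
    return total / (p * p)


def mrmr_rank(
    table: FeatureTable, bins: int = DEFAULT_BINS
) -> FeatureRanking:
    """Greedy mRMR ranking of all features (MID difference criterion).

    The first feature maximizes relevance alone; each subsequent pick
    maximizes I(X, c) - (1/|S|) * sum_{Xj in S} I(X, Xj) over the unselected
    features X, with lexicographic tie-breaking.
    """
    names = sorted(table.feature_names)
    labels = table.labels
    if len(names) < 2:
        return FeatureRanking(
            features=list(names),
            scores=[
                mutual_information(table.x[n].to_numpy(), labels, bins).value
                for n in names
            ],
        )
    cols = {n: discretize(table.x[n].to_numpy(), bins) for n in names}
    yc = discretize(labels, bins)
    rel = {n: _discrete_mi(cols[n], yc) for n in names}
    pair_cache: dict[tuple[str, str], float] = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = _discrete_mi(cols[a], cols[b])
        return pair_cache[key]

    selected: list[str] = []
    scores: list[float] = []
    remaining = list(names)
    while remaining:
        best_name, best_score = None, -np.inf
        for n in remaining:  # remaining stays sorted -> lexicographic ties
            if selected:
                red = np.mean([pair_mi(n, s) for s in selected])
                score = rel[n] - red
            else:
                score = rel[n]
            if score > best_score:
                best_name, best_score = n, score
        selected.append(best_name)
        scores.append(float(best_score))
        remaining.remove(best_name)
    return FeatureRanking(features=selected, scores=scores)


def _stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment; returns test-index arrays."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def incremental_select(
    ranking: FeatureRanking,
    table: FeatureTable,
    classifier_factory: Callable[[], "object"],
    n_folds: int = 5,
    seed: int = 17,
    metric: Optional[Callable[[np.ndarray, np.ndarray], Optional[float]]] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the top-k ranking prefix with the best cross-validated F-measure.

    For each prefix size k the classifier is trained/evaluated by stratified
    ``n_folds``-fold cross-validation (pooled confusion counts across folds).
    Returns the winning prefix (ties favor the smaller k) and the full
    per-k score table. A classifier failure at some k is recorded as a
    missing score and the scan continues.
    """
    if metric is None:
        from .evaluation import f_measure_from_labels

        metric = f_measure_from_labels
    folds = _stratified_folds(table.labels, n_folds, seed)
    all_idx = np.arange(table.n)
    records = []
    best_k, best_score = None, -np.inf
    for k in range(1, len(ranking.features) + 1):
        prefix = ranking.features[:k]
        sub = table.subset_features(prefix)
        try:
            preds = np.empty(table.n, dtype=int)
            for test_idx in folds:
                train_idx = np.setdiff1d(all_idx, test_idx)
                clf = classifier_factory()
                clf.fit(sub.subset_rows(train_idx))
                preds[test_idx] = clf.predict(sub.x.iloc[test_idx].to_numpy())
            score = metric(preds, table.labels)
        except Exception as exc:  # noqa: BLE001 - per-contract: record and continue
            logger.warning("classifier failed at k=%d: %s", k, exc)
            score = None
        records.append({"k": k, "f_measure": score})
        if score is not None and score > best_score:
            best_k, best_score = k, score
    score_table = pd.DataFrame(records)
    if best_k is None:
        raise RuntimeError("classifier failed at every prefix size")
    return ranking.features[:best_k], score_table
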