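"""Density clustering of predicted hot spots into predicted hot regions.

A from-scratch DBSCAN over alpha-carbon coordinates: a residue whose closed
Euclidean eps-ball (the residue itself included) contains at least ``min_pts``
residues is a *core* residue; clusters are the transitive expansion of core
residues through their neighborhoods, and residues reachable from no core are
noise. Predicted hot spots that land in noise are discarded — the clustering
stage acts as a second filter on the classifier's false positives.

Clustering is always per complex; coordinates from different complexes are
never mixed. The (min_pts, eps) pair is chosen by grid search maximizing the
region-level F-measure against the standard hot regions, with the grid
honoring the biological bounds min_pts >= 3 (a hot region has at least three
hot spots) and eps <= 9.5 A (the largest contact distance observed between
amino acids in one hot region).
"""

from __future__ import annotations

import warnings
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labeling import LabeledResidue

NOISE = -1

DEFAULT_MIN_GRID = (3, 4, 5, 6)
DEFAULT_EPS_GRID = tuple(np.arange(4.0, 9.51, 0.5))


@dataclass(frozen=True)
class DBSCANParams:
    min_pts: int
    eps: float

    def __post_init__(self):
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class HotRegion:
    """A set of residues forming one hot region, predicted or standard."""

    region_id: str
    members: list[tuple[str, str, int]]  # (complex, chain, position)
    source: str  # "predicted" | "standard"
    complex_id: str

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def dbscan(points: Sequence[np.ndarray], params: DBSCANParams) -> np.ndarray:
    """Cluster 3-D points; returns a cluster id per point, -1 for noise.

    Points are visited in input order, which together with the closed-ball
    neighborhood rule makes the labeling deterministic: a border point
    reachable from several clusters joins the cluster whose core reaches it
    first. Callers wanting reproducible runs pass points in a canonical
    (chain, position) order.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.array([], dtype=int)
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    # closed eps-ball, self included
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    adjacency = d2 <= params.eps**2
    neighbor_counts = adjacency.sum(axis=1)
    is_core = neighbor_counts >= params.min_pts

    labels = np.full(n, NOISE, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cluster = 0
    for i in range(n):
        if visited[i] or not is_core[i]:
            continue
        # expand a new cluster from this core point
        queue = deque([i])
        visited[i] = True
        labels[i] = cluster
        while queue:
            j = queue.popleft()
            if not is_core[j]:
                continue
            for k in np.flatnonzero(adjacency[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster
                if not visited[k]:
                    visited[k] = True
                    queue.append(k)
        cluster += 1
    return labels


def predict_regions(
    residues: Sequence[LabeledResidue], params: DBSCANParams
) -> list[HotRegion]:
    """DBSCAN the predicted hot spots of each complex into predicted regions.

    Residues without a coordinate are skipped with a warning; noise points
    are dropped. Region ids are ``<complex>:P<k>`` in deterministic order.
    """
    by_complex: dict[str, list[LabeledResidue]] = defaultdict(list)
    for r in residues:
        if r.ca is None:
            warnings.warn(f"residue {r.site} has no coordinate; skipped", stacklevel=2)
            continue
        by_complex[r.complex_id].append(r)
    regions: list[HotRegion] = []
    for cid in sorted(by_complex):
        members = sorted(by_complex[cid], key=lambda r: (r.chain, r.position))
        labels = dbscan([r.ca for r in members], params)
        for cluster_id in sorted(set(labels) - {NOISE}):
            sites = [m.site for m, l in zip(members, labels) if l == cluster_id]
            regions.append(
                HotRegion(
                    region_id=f"{cid}:P{cluster_id}",
                    members=sites,
                    source="predicted",
                    complex_id=cid,
                )
            )
    return regions


@dataclass
class GridSearchResult:
    best: DBSCANParams
    best_score: Optional[float]
    table: pd.DataFrame = field(repr=False)


def grid_search(
    predicted_hot: Sequence[LabeledResidue],
    standard_regions: Sequence[HotRegion],
    min_grid: Sequence[int] = DEFAULT_MIN_GRID,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    coverage: float = 0.6,
) -> GridSearchResult:
    """Choose (min_pts, eps) maximizing region-level F-measure.

    Every grid point is scored by matching the resulting predicted regions
    against the standard regions (60%-coverage rule by default). An undefined
    F-measure ranks below any number. Ties prefer smaller min_pts, then
    smaller eps. The full score table is returned for reporting.
    """
    from .evaluation import match_regions, region_metrics

    if not min_grid or not len(eps_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    best: Optional[DBSCANParams] = None
    best_score: Optional[float] = None
    for min_pts in sorted(min_grid):
        for eps in sorted(eps_grid):
            params = DBSCANParams(min_pts=min_pts, eps=float(eps))
            predicted = predict_regions(predicted_hot, params)
            counts = match_regions(predicted, standard_regions, coverage)
            f = region_metrics(counts).f_measure
            rows.append(
                {
                    "min_pts": min_pts,
                    "eps": float(eps),
                    "n_predicted_regions": len(predicted),
                    "f_measure": f,
                }
            )
            if f is not None and (best_score is None or f > best_score):
                best, best_score = params, f
    if best is None:  # every grid point undefined: fall back to first point
        best = DBSCANParams(min_pts=sorted(min_grid)[0], eps=float(sorted(eps_grid)[0]))
    return GridSearchResult(best=best, best_score=best_score, table=pd.DataFrame(rows))


def regions_to_frame(regions: Sequence[HotRegion]) -> pd.DataFrame:
    rows = []
    for reg in regions:
        for complex_id, chain, position in reg.members:
            rows.append(
                {
                    "complex": complex_id,
                    "region_id": reg.region_id,
                    "chain": chain,
                    "position": position,
                    "source": reg.source,
                }
            )
    return pd.DataFrame(rows, columns=["complex", "region_id", "chain", "position", "source"])
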