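"""DBSCAN correctness against a brute-force density-reachability oracle."""

import numpy as np
import pytest

from hotregion.clustering import (
    DBSCANParams,
    DEFAULT_EPS_GRID,
    DEFAULT_MIN_GRID,
    dbscan,
    grid_search,
    predict_regions,
)
from hotregion.labeling import LabeledResidue
from hotregion.standard_regions import build_standard_regions


def oracle_check(points, params, labels):
    """Verify a labeling against the density-reachability definition.

    Characterizes any valid DBSCAN output: core points sharing a label iff
    density-connected, border points attached to a reachable core's cluster,
    everything else noise. Core membership/components are computed here by
    plain double loops, independently of the implementation under test.
    """
    n = len(points)
    pts = np.asarray(points)
    eps2 = params.eps**2
    within = [
        [j for j in range(n) if np.sum((pts[i] - pts[j]) ** 2) <= eps2]
        for i in range(n)
    ]
    core = [len(within[i]) >= params.min_pts for i in range(n)]

    # components of the core graph via repeated sweeps (no union-find reuse)
    comp = [-1] * n
    c = 0
    for i in range(n):
        if not core[i] or comp[i] != -1:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            u = stack.pop()
            for v in within[u]:
                if core[v] and comp[v] == -1:
                    comp[v] = c
                    stack.append(v)
        c += 1

    for i in range(n):
        if core[i]:
            assert labels[i] >= 0, f"core point {i} labeled noise"
        elif any(core[j] for j in within[i]):  # border point
            reachable = {comp[j] for j in within[i] if core[j]}
            core_labels = {labels[j] for j in range(n) if core[j] and comp[j] in reachable}
            assert labels[i] in core_labels, f"border point {i} in wrong cluster"
        else:
            assert labels[i] == -1, f"unreachable point {i} not noise"
    # cores agree with components exactly (same label iff same component)
    for i in range(n):
        for j in range(n):
            if core[i] and core[j]:
                assert (labels[i] == labels[j]) == (comp[i] == comp[j])


def residue(cid, pos, xyz, chain="A"):
    return LabeledResidue(cid, chain, pos, "TRP", 2.0, "hot", np.asarray(xyz, float))


class TestDbscan:
    def test_tight_cluster_no_noise(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 0.5, (5, 3))
        labels = dbscan(pts, DBSCANParams(min_pts=3, eps=5.0))
        assert set(labels) == {0}

    def test_isolated_point_is_noise(self):
        labels = dbscan([np.zeros(3)], DBSCANParams(min_pts=3, eps=5.0))
        assert list(labels) == [-1]

    def test_empty_input(self):
        assert dbscan([], DBSCANParams(min_pts=3, eps=5.0)).size == 0

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        eps = 4.0
        blob1 = rng.normal(0, 1, (6, 3))
        blob2 = rng.normal(0, 1, (6, 3)) + np.array([10 * eps, 0, 0])
        pts = np.vstack([blob1, blob2])
        params = DBSCANParams(min_pts=3, eps=eps)
        labels = dbscan(pts, params)
        assert len(set(labels) - {-1}) == 2
        oracle_check(pts, params, labels)

    @pytest.mark.parametrize("min_pts", DEFAULT_MIN_GRID)
    def test_matches_reachability_oracle_random_instances(self, min_pts):
        rng = np.random.default_rng(min_pts)
        for trial in range(60):
            n = int(rng.integers(1, 31))
            pts = rng.uniform(0, 25, (n, 3))
            for eps in DEFAULT_EPS_GRID[::3]:
                params = DBSCANParams(min_pts=min_pts, eps=float(eps))
                oracle_check(pts, params, dbscan(pts, params))

    def test_noise_count_monotone_in_eps(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 30, (25, 3))
        noise_counts = [
            int(np.sum(dbscan(pts, DBSCANParams(3, eps)) == -1))
            for eps in DEFAULT_EPS_GRID
        ]
        assert all(a >= b for a, b in zip(noise_counts, noise_counts[1:]))

    def test_members_within_eps_of_a_core(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 15, (20, 3))
        params = DBSCANParams(min_pts=3, eps=6.0)
        labels = dbscan(pts, params)
        core = [
            i
            for i in range(len(pts))
            if np.sum(np.sum((pts - pts[i]) ** 2, axis=1) <= params.eps**2)
            >= params.min_pts
        ]
        for i, l in enumerate(labels):
            if l == -1:
                continue
            assert any(
                labels[j] == l and np.linalg.norm(pts[i] - pts[j]) <= params.eps
                for j in core
            )


class TestPredictRegions:
    def test_single_tight_cluster(self):
        rng = np.random.default_rng(4)
        residues = [
            residue("1ABC", i + 1, rng.normal(0, 1.0, 3)) for i in range(4)
        ]
        regions = predict_regions(residues, DBSCANParams(min_pts=4, eps=8.5))
        assert len(regions) == 1
        assert len(regions[0]) == 4

    def test_too_few_hot_spots_no_region(self):
        residues = [residue("1ABC", 1, [0, 0, 0]), residue("1ABC", 2, [1, 0, 0])]
        assert predict_regions(residues, DBSCANParams(3, 9.5)) == []

    def test_regions_never_cross_complexes(self):
        rng = np.random.default_rng(5)
        residues = [residue("AAA", i + 1, rng.normal(0, 1, 3)) for i in range(5)]
        residues += [residue("BBB", i + 1, rng.normal(0, 1, 3)) for i in range(5)]
        regions = predict_regions(residues, DBSCANParams(3, 9.5))
        assert len(regions) == 2
        assert {r.complex_id for r in regions} == {"AAA", "BBB"}

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        residues = [
            residue("X", i + 1, rng.uniform(0, 20, 3)) for i in range(15)
        ]
        params = DBSCANParams(3, 6.5)
        baseline = {r.member_set for r in predict_regions(residues, params)}
        for _ in range(5):
            shuffled = list(residues)
            rng.shuffle(shuffled)
            assert {r.member_set for r in predict_regions(shuffled, params)} == baseline

    def test_missing_coordinate_warns_and_skips(self):
        residues = [
            LabeledResidue("X", "A", 1, "TRP", 2.0, "hot", None),
        ]
        with pytest.warns(UserWarning):
            assert predict_regions(residues, DBSCANParams(3, 9.5)) == []


class TestGridSearch:
    def planted(self, seed=7):
        rng = np.random.default_rng(seed)
        residues = []
        pos = 1
        for cid in ("C1", "C2"):
            for center in (np.zeros(3), np.array([40.0, 0, 0])):
                for _ in range(5):
                    residues.append(residue(cid, pos, center + rng.normal(0, 1.2, 3)))
                    pos += 1
        return residues

    def test_recovers_parameters_scoring_perfectly(self):
        residues = self.planted()
        standard = build_standard_regions(residues)
        result = grid_search(residues, standard)
        assert result.best_score == 1.0
        assert result.best.min_pts >= 3
        assert result.best.eps <= 9.5

    def test_single_point_grid(self):
        residues = self.planted()
        standard = build_standard_regions(residues)
        result = grid_search(residues, standard, min_grid=[4], eps_grid=[8.5])
        assert (result.best.min_pts, result.best.eps) == (4, 8.5)
        assert len(result.table) == 1

    def test_score_table_covers_full_grid(self):
        residues = self.planted()
        standard = build_standard_regions(residues)
        result = grid_search(residues, standard, min_grid=[3, 4], eps_grid=[4.0, 6.0, 9.5])
        assert len(result.table) == 6

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], [], min_grid=[], eps_grid=[4.0])
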