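"""Mutual information estimation and mRMR ranking against enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from hotregion.gnb import GaussianNaiveBayes
from hotregion.mrmr import (
    incremental_select,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)
from tests.conftest import make_table


def enumerate_mi(x, y):
    """Independent plug-in MI oracle: joint counts via plain dict loops."""
    n = len(x)
    joint, px, py = {}, {}, {}
    for xi, yi in zip(x, y):
        joint[(xi, yi)] = joint.get((xi, yi), 0) + 1
        px[xi] = px.get(xi, 0) + 1
        py[yi] = py.get(yi, 0) + 1
    total = 0.0
    for (xi, yi), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((px[xi] / n) * (py[yi] / n)))
    return total


class TestMutualInformation:
    def test_constant_column_gives_zero(self):
        x = np.zeros(20)
        y = np.arange(20) % 2
        assert mutual_information(x, y).value == 0.0

    def test_perfectly_dependent_binary_pair_is_ln2(self):
        # x = y, each value probability 1/2: enumerating the 2x2 joint gives
        # I = 2 * (1/2) log( (1/2) / (1/4) ) = ln 2
        x = np.array([0, 1] * 10)
        assert mutual_information(x, x).value == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_pair_is_zero(self):
        x = np.array([0, 0, 1, 1] * 5)
        y = np.array([0, 1, 0, 1] * 5)
        assert mutual_information(x, y).value == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))

    def test_matches_enumeration_oracle_on_random_discrete_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.integers(0, 4, 60)
            y = rng.integers(0, 3, 60)
            ours = mutual_information(x, y, bins=10).value
            assert ours == pytest.approx(enumerate_mi(x, y), abs=1e-12)
            # symmetry
            assert ours == pytest.approx(mutual_information(y, x, bins=10).value)

    def test_data_processing_inequality_on_bin_merges(self):
        # merging x's categories can never increase information about y
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 6, 80)
            y = rng.integers(0, 3, 80)
            merged = x // 2
            assert enumerate_mi(x, y) >= enumerate_mi(merged, y) - 1e-12


class TestRelevanceRedundancy:
    def test_singleton_relevance_is_feature_label_mi(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 2, 50)
        table = make_table(x.reshape(-1, 1), y)
        assert relevance(table.x, y) == pytest.approx(enumerate_mi(x, y), abs=1e-12)

    def test_duplicated_feature_same_relevance_as_singleton(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 50).astype(float)
        y = rng.integers(0, 2, 50)
        single = make_table(x.reshape(-1, 1), y)
        double = make_table(np.column_stack([x, x]), y)
        assert relevance(double.x, y) == pytest.approx(relevance(single.x, y))

    def test_singleton_redundancy_is_own_entropy(self):
        # the literal 1/|F|^2 sum over ordered pairs includes i=j: I(X,X) = H(X)
        x = np.array([0, 0, 1, 2] * 10).astype(float)
        table = make_table(x.reshape(-1, 1), np.zeros(40))
        entropy = enumerate_mi(x, x)
        assert redundancy(table.x) == pytest.approx(entropy, abs=1e-12)

    def test_identical_pair_more_redundant_than_independent_pair(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 200).astype(float)
        z = rng.integers(0, 2, 200).astype(float)
        identical = make_table(np.column_stack([x, x]), np.zeros(200))
        independent = make_table(np.column_stack([x, z]), np.zeros(200))
        assert redundancy(identical.x) > redundancy(independent.x)

    def test_pair_normalization_divides_by_four(self):
        x = np.array([0, 1] * 20).astype(float)
        pair = make_table(np.column_stack([x, x]), np.zeros(40))
        h = enumerate_mi(x, x)
        # all four ordered pairs have MI = H(x); sum 4H / 4 = H
        assert redundancy(pair.x) == pytest.approx(h, abs=1e-12)

    def test_empty_set_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            relevance(pd.DataFrame(), np.zeros(5))
        with pytest.raises(ValueError):
            redundancy(pd.DataFrame())


class TestMrmrRank:
    def dataset(self, seed=3, n=200):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        perfect = y.astype(float)
        noise1 = rng.normal(size=n)
        noise2 = rng.normal(size=n)
        return y, perfect, noise1, noise2

    def test_perfect_feature_ranked_first(self):
        y, perfect, noise1, noise2 = self.dataset()
        table = make_table(
            np.column_stack([noise1, perfect, noise2]), y,
            names=["noise_a", "perfect", "noise_b"],
        )
        ranking = mrmr_rank(table)
        assert ranking.features[0] == "perfect"
        # first element maximizes relevance computed independently
        rels = {
            name: mutual_information(table.x[name].to_numpy(), y).value
            for name in table.feature_names
        }
        assert ranking.features[0] == max(sorted(rels), key=rels.get)

    def test_redundant_copy_demoted(self):
        rng = np.random.default_rng(4)
        n = 400
        y = rng.integers(0, 2, n)
        best = y + rng.normal(0, 0.1, n)
        # informative but independent signal: correlated with y differently
        other = y * 2.0 + rng.normal(0, 0.6, n)
        table = make_table(
            np.column_stack([best, best.copy(), other]), y,
            names=["best", "best_copy", "other"],
        )
        ranking = mrmr_rank(table)
        assert ranking.features[0] in ("best", "best_copy")
        assert ranking.features[1] == "other"  # the copy is pure redundancy

    def test_ranking_is_permutation(self):
        y, a, b, c = self.dataset(seed=5)
        table = make_table(np.column_stack([a, b, c]), y, names=["a", "b", "c"])
        ranking = mrmr_rank(table)
        assert sorted(ranking.features) == ["a", "b", "c"]

    def test_greedy_step_matches_exhaustive_mid_score(self):
        # second pick maximizes I(X,c) - mean MI with the selected set,
        # verified by recomputing every candidate's score from the raw MIs
        rng = np.random.default_rng(6)
        n = 150
        y = rng.integers(0, 2, n)
        cols = {f"f{i}": rng.integers(0, 3, n).astype(float) for i in range(4)}
        cols["sig"] = y + rng.normal(0, 0.2, n)
        names = sorted(cols)
        table = make_table(np.column_stack([cols[k] for k in names]), y, names=names)
        ranking = mrmr_rank(table, bins=10)
        first = ranking.features[0]
        scores = {}
        for cand in names:
            if cand == first:
                continue
            rel = mutual_information(table.x[cand].to_numpy(), y).value
            red = mutual_information(
                table.x[cand].to_numpy(), table.x[first].to_numpy()
            ).value
            scores[cand] = rel - red
        expected_second = max(sorted(scores), key=scores.get)
        assert ranking.features[1] == expected_second


class TestIncrementalSelect:
    def test_planted_signal_selected(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.integers(0, 2, n)
        signal = np.where(y == 1, 3.0, 0.0) + rng.normal(0, 1, n)
        noise = rng.normal(size=(n, 4))
        table = make_table(
            np.column_stack([signal, noise]), y,
            names=["signal", "n1", "n2", "n3", "n4"],
        )
        ranking = mrmr_rank(table)
        selected, scores = incremental_select(
            ranking, table, GaussianNaiveBayes, seed=17
        )
        assert "signal" in selected
        best = scores.f_measure.dropna().max()
        at_full = scores.f_measure.iloc[-1]
        assert best >= at_full

    def test_single_feature_prefix(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 60)
        table = make_table((y + rng.normal(0, 0.5, 60)).reshape(-1, 1), y, names=["only"])
        ranking = mrmr_rank(table)
        selected, _ = incremental_select(ranking, table, GaussianNaiveBayes, seed=17)
        assert selected == ["only"]
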