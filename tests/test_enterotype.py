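"""PAM, the distance-based CH index, K selection, silhouettes, transitions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from weanotype import enterotype
from weanotype.enterotype import (
    ch_index,
    choose_k,
    cluster_at_k,
    pam,
    silhouette_validation,
    transitions,
)
from weanotype.tables import RelAbundanceTable
from tests.conftest import make_metadata


def _dm(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return squareform(pdist(pts))


def _pam_cost(D, medoids):
    return D[np.asarray(medoids)].min(axis=0).sum()


def _exhaustive_best_cost(D, k):
    n = D.shape[0]
    return min(_pam_cost(D, c) for c in itertools.combinations(range(n), k))


class TestPam:
    def test_colinear_points_split_correctly(self):
        D = _dm([0.0, 1.0, 10.0, 11.0])
        labels, medoids = pam(D, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert _pam_cost(D, medoids) == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [2, 3])
    def test_near_exhaustive_and_swap_optimal(self, k):
        """BUILD+SWAP is a local search: it must end swap-local-optimal and
        close to the exhaustive optimum (equal on most instances)."""
        rng = np.random.default_rng(0)
        exact = 0
        for trial in range(8):
            D = _dm(rng.normal(size=(12, 2)))
            _, medoids = pam(D, k)
            cost = _pam_cost(D, medoids)
            best = _exhaustive_best_cost(D, k)
            assert cost <= best * 1.1 + 1e-9
            exact += cost == pytest.approx(best, rel=1e-9)
            # no single medoid swap can improve the returned solution
            for mi in range(k):
                for h in range(12):
                    if h in medoids:
                        continue
                    alt = list(medoids)
                    alt[mi] = h
                    assert _pam_cost(D, alt) >= cost - 1e-9
        assert exact >= 4

    def test_k_n_minus_one_leaves_one_pair(self):
        D = _dm(np.arange(6.0) ** 1.3)
        labels, _ = pam(D, 5)
        sizes = sorted(np.bincount(labels))
        assert sizes == [1, 1, 1, 1, 2]

    def test_duplicated_dataset_preserves_partition(self):
        rng = np.random.default_rng(1)
        pts = np.r_[rng.normal(0, 0.3, size=(6, 2)), rng.normal(5, 0.3, size=(6, 2))]
        labels1, _ = pam(_dm(pts), 2)
        labels2, _ = pam(_dm(np.r_[pts, pts]), 2)
        # doubling every point must not change which points cluster together
        assert (labels2[:12] == labels2[12:]).all()
        same1 = labels1[:, None] == labels1[None, :]
        same2 = labels2[:12, None] == labels2[None, :12]
        assert (same1 == same2).all()

    def test_invalid_k_rejected(self):
        D = _dm(np.arange(4.0))
        with pytest.raises(ValueError):
            pam(D, 4)
        with pytest.raises(ValueError):
            pam(D, 1)


class TestChIndex:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        D = _dm(rng.normal(size=(15, 3)))
        labels = rng.integers(0, 3, size=15)
        labels[:3] = [0, 1, 2]  # guarantee non-empty clusters
        n, k = 15, 3
        total = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        within = 0.0
        for g in range(k):
            idx = [i for i in range(n) if labels[i] == g]
            within += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        expected = ((total - within) / (k - 1)) / (within / (n - k))
        assert ch_index(D, labels) == pytest.approx(expected, rel=1e-9)

    def test_euclidean_case_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        X[20:] += 3.0
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert ch_index(_dm(X), labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9
        )

    def test_correct_labels_beat_random_relabelings(self):
        rng = np.random.default_rng(4)
        X = np.r_[rng.normal(0, 0.2, size=(15, 2)), rng.normal(4, 0.2, size=(15, 2))]
        D = _dm(X)
        truth = np.r_[np.zeros(15, int), np.ones(15, int)]
        ch_true = ch_index(D, truth)
        for _ in range(100):
            assert ch_true > ch_index(D, rng.permutation(truth))

    def test_degenerate_zero_within_returns_inf(self):
        D = _dm([0.0, 0.0, 5.0, 5.0])
        assert ch_index(D, np.array([0, 0, 1, 1])) == np.inf

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ch_index(_dm(np.arange(4.0)), np.zeros(4, int))


def _mixture_table(rng, n, centers, theta=800.0):
    rows, truth = [], []
    for i in range(n):
        z = i % len(centers)
        rows.append(rng.dirichlet(theta * np.asarray(centers[z])))
        truth.append(z)
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)],
                      columns=[f"g{j}" for j in range(len(centers[0]))])
    df = df.div(df.sum(axis=1), axis=0)
    return RelAbundanceTable(df), np.array(truth)


class TestChooseK:
    def test_two_component_mixture_selects_k2(self):
        rng = np.random.default_rng(5)
        rel, truth = _mixture_table(
            rng, 80, [[0.6, 0.2, 0.1, 0.1], [0.1, 0.1, 0.2, 0.6]])
        sol = choose_k(rel, (2, 6))
        assert sol.k == 2
        recovered = sol.labels.to_numpy()
        same = (recovered[truth == 0][0] == recovered[truth == 0]).all()
        assert same and (recovered[truth == 1][0] == recovered[truth == 1]).all()

    def test_structureless_data_flagged_weak(self):
        rng = np.random.default_rng(6)
        rel, _ = _mixture_table(rng, 200, [[0.25, 0.25, 0.25, 0.25]], theta=50.0)
        sol = choose_k(rel, (2, 6))
        assert sol.weak_structure

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        rel, _ = _mixture_table(
            rng, 60, [[0.6, 0.2, 0.1, 0.1], [0.1, 0.1, 0.2, 0.6], [0.25, 0.5, 0.15, 0.1]])
        sol = choose_k(rel, (2, 5))
        perm = rng.permutation(len(rel.data))
        shuffled = RelAbundanceTable(rel.data.iloc[perm])
        sol2 = choose_k(shuffled, (2, 5))
        assert sol2.k == sol.k
        a = sol.labels.reindex(sol2.labels.index)
        same = (a.to_numpy()[:, None] == a.to_numpy()[None, :])
        same2 = (sol2.labels.to_numpy()[:, None] == sol2.labels.to_numpy()[None, :])
        assert (same == same2).all()

    def test_k_range_shrinks_with_warning(self):
        rng = np.random.default_rng(8)
        rel, _ = _mixture_table(rng, 6, [[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
        with pytest.warns(UserWarning, match="shrinking"):
            sol = choose_k(rel, (2, 10))
        assert sol.k < 6


class TestSilhouette:
    def test_separated_clusters_approach_one(self):
        rng = np.random.default_rng(9)
        rel, _ = _mixture_table(
            rng, 40, [[0.97, 0.01, 0.01, 0.01], [0.01, 0.01, 0.01, 0.97]], theta=5000.0)
        sol = cluster_at_k(rel, 2)
        assert sol.mean_silhouette > 0.9

    def test_random_labels_on_structureless_data_near_zero(self):
        rng = np.random.default_rng(10)
        from sklearn.metrics import silhouette_samples
        rel, _ = _mixture_table(rng, 200, [[0.25, 0.25, 0.25, 0.25]], theta=60.0)
        from weanotype.diversity import distance
        d = distance(rel, "jsd").values
        s = silhouette_samples(d, rng.integers(0, 2, size=200), metric="precomputed")
        assert abs(s.mean()) < 0.1
        assert s.min() >= -1 and s.max() <= 1

    def test_validation_reports_null_and_percentile(self):
        rng = np.random.default_rng(11)
        rel, _ = _mixture_table(
            rng, 50, [[0.6, 0.2, 0.1, 0.1], [0.1, 0.1, 0.2, 0.6]])
        sol = cluster_at_k(rel, 2)
        sol = silhouette_validation(rel, sol, n_subsets=15, seed=0)
        assert len(sol.silhouette_null) == 15
        assert 0 <= sol.silhouette_percentile <= 100
        assert np.all(np.abs(sol.silhouette_null) <= 1)


class TestTransitions:
    def test_identical_labels_give_zero_shift(self):
        meta = make_metadata(n_pigs=4)
        labels = pd.Series("E1", index=meta.data.index, name="enterotype")
        tm = transitions(labels, meta)
        assert tm.shift_fraction == 0.0
        assert tm.n_pigs == 4

    def test_hand_built_three_of_four_switch(self):
        meta = make_metadata(n_pigs=4)
        lab = {}
        for i, pig in enumerate(sorted(meta.data["pig_id"].unique())):
            lab[f"{pig}.d26"] = "E1"
            lab[f"{pig}.d35"] = "E1" if i == 0 else "E2"
        labels = pd.Series(lab, name="enterotype")
        tm = transitions(labels, meta)
        assert tm.shift_fraction == pytest.approx(0.75)
        assert tm.counts.loc["E1", "E2"] == 3
        assert tm.probabilities.loc["E1"].sum() == pytest.approx(1.0)

    def test_no_complete_pig_is_an_error(self):
        meta = make_metadata(n_pigs=2)
        d26_only = meta.data[meta.data["age_point"] == "d26"]
        labels = pd.Series("E1", index=d26_only.index, name="enterotype")
        with pytest.raises(ValueError):
            transitions(labels, meta)
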