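"""Hierarchical clustering, validity-index voting, profile comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from blinkcr.score import LEARNING_COLUMNS, learning_matrix_from_truth
from blinkcr.stats import one_way_anova
from blinkcr.subtype import (
    complete_linkage,
    compare_profiles,
    cut_tree,
    label_profiles,
    majority_rule_k,
    run_subtype,
    sq_euclidean_matrix,
    validity_indices,
)
from blinkcr.synthdata import LearningProfile, ProfileName, sample_cohort, simulate_study


def _partition_set(labels):
    out = {}
    for i, c in enumerate(labels):
        out.setdefault(c, set()).add(i)
    return frozenset(frozenset(v) for v in out.values())


def _naive_complete_linkage_partitions(D):
    """O(n^3) agglomeration oracle: returns partitions for every k."""
    n = D.shape[0]
    clusters = [{i} for i in range(n)]
    partitions = {n: [set(c) for c in clusters]}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
        partitions[len(clusters)] = [set(c) for c in clusters]
    return partitions


class TestDistances:
    def test_identical_rows_zero(self):
        X = np.ones((3, 9))
        D = sq_euclidean_matrix(X)
        assert np.allclose(D, 0.0)

    def test_known_distance(self):
        X = np.vstack([np.zeros(9), np.full(9, 10.0)])
        assert sq_euclidean_matrix(X)[0, 1] == pytest.approx(900.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 9))
        D = sq_euclidean_matrix(X)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(
                    np.sum((X[i] - X[j]) ** 2), abs=1e-9
                )
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_missing_values_rejected(self):
        X = np.ones((3, 9))
        X[1, 4] = np.nan
        with pytest.raises(ValueError):
            sq_euclidean_matrix(X)


class TestLinkage:
    def test_two_points(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        Z = complete_linkage(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_hand_trace_one_dimensional(self):
        # points {0, 1, 10} with squared distances: first merge {0,1} at 1,
        # final merge at 100
        pts = np.array([[0.0], [1.0], [10.0]])
        Z = complete_linkage(sq_euclidean_matrix(pts))
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(100.0)
        labels = cut_tree(Z, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_monotone_heights(self):
        rng = np.random.default_rng(1)
        Z = complete_linkage(sq_euclidean_matrix(rng.normal(size=(20, 9))))
        assert np.all(np.diff(Z[:, 2]) >= 0)

    def test_matches_naive_oracle_small_instances(self):
        rng = np.random.default_rng(2)
        for n in range(3, 8):
            for rep in range(30):
                X = rng.normal(size=(n, 3))
                D = sq_euclidean_matrix(X)
                Z = complete_linkage(D)
                oracle = _naive_complete_linkage_partitions(D)
                for k in range(1, n + 1):
                    mine = _partition_set(cut_tree(Z, k))
                    ref = frozenset(frozenset(c) for c in oracle[k])
                    assert mine == ref, (n, rep, k)

    def test_cut_extremes(self):
        rng = np.random.default_rng(3)
        Z = complete_linkage(sq_euclidean_matrix(rng.normal(size=(6, 2))))
        assert len(set(cut_tree(Z, 1))) == 1
        assert len(set(cut_tree(Z, 6))) == 6
        with pytest.raises(ValueError):
            cut_tree(Z, 7)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 9))
        perm = rng.permutation(12)
        Z1 = complete_linkage(sq_euclidean_matrix(X))
        Z2 = complete_linkage(sq_euclidean_matrix(X[perm]))
        l1 = cut_tree(Z1, 3)
        l2 = cut_tree(Z2, 3)
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_scale_invariance_of_partitions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 9))
        Z1 = complete_linkage(sq_euclidean_matrix(X))
        Z2 = complete_linkage(sq_euclidean_matrix(X * 7.3))
        for k in range(2, 8):
            assert _partition_set(cut_tree(Z1, k)) == _partition_set(cut_tree(Z2, k))


class TestValidityIndices:
    def _two_clouds(self, rng, n=40, sep=10.0):
        X = rng.normal(size=(n, 2))
        X[n // 2 :] += sep * np.sqrt(2)  # ~10 within-SDs apart per axis
        return X

    def test_separated_clouds_select_k2(self):
        """Two well-separated clouds: every extremum-rule index votes k=2
        (difference-rule indices cannot select the boundary k by
        construction), and the majority vote lands on 2."""
        from blinkcr.subtype import _INDEX_RULE

        rng = np.random.default_rng(6)
        X = self._two_clouds(rng)
        tree = complete_linkage(sq_euclidean_matrix(X))
        labels_by_k = {k: cut_tree(tree, k) for k in range(2, 9)}
        votes, scores = validity_indices(X, labels_by_k)
        # McClain-Rao's within/between mean-distance ratio keeps shrinking as
        # tight clouds are subdivided, so it drifts to large k even here
        consensus = {
            "calinski_harabasz", "silhouette", "dunn", "davies_bouldin",
            "ratkowsky_lance", "c_index", "point_biserial",
        }
        assert consensus <= set(votes)
        assert all(votes[n] == 2 for n in consensus), votes
        assert majority_rule_k(votes) == 2

    def test_perfect_partition_silhouette(self):
        # two clusters of coincident points: silhouette attains its bound 1
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 4.0)])
        labels_by_k = {2: np.repeat([0, 1], 5)}
        _, scores = validity_indices(X, labels_by_k)
        assert scores.loc["silhouette", 2] == pytest.approx(1.0)

    def test_calinski_harabasz_closed_form(self):
        X = np.array([[0.0], [1.0], [4.0], [5.0]])
        labels_by_k = {2: np.array([0, 0, 1, 1])}
        _, scores = validity_indices(X, labels_by_k)
        # SSB = 4 * (2.25^2) ... closed form on this 1-D instance:
        grand = X.mean()
        ssb = 2 * (0.5 - grand) ** 2 + 2 * (4.5 - grand) ** 2
        ssw = 0.5 + 0.5
        expected = (ssb / 1) / (ssw / 2)
        assert scores.loc["calinski_harabasz", 2] == pytest.approx(
            float(expected), abs=1e-9
        )

    def test_degenerate_partition_rejected(self):
        X = np.random.default_rng(7).normal(size=(10, 2))
        with pytest.raises(ValueError):
            validity_indices(X, {3: np.repeat([0, 1], 5)})


class TestMajorityRule:
    def test_plurality(self):
        votes = {f"i{j}": k for j, k in enumerate([2, 3, 3, 3, 3, 3, 4, 4])}
        assert majority_rule_k(votes) == 3

    def test_tie_breaks_small(self):
        votes = {"a": 2, "b": 2, "c": 2, "d": 3, "e": 3, "f": 3}
        assert majority_rule_k(votes) == 2

    def test_no_votes(self):
        with pytest.raises(ValueError):
            majority_rule_k({})


class TestProfiles:
    def test_labels_by_descending_mean(self):
        X = np.vstack(
            [np.full((4, 9), 60.0), np.full((4, 9), 35.0), np.full((4, 9), 10.0)]
        )
        labels = np.repeat([0, 1, 2], 4)
        names = label_profiles(X, labels)
        assert names == {0: "HIGH", 1: "MID", 2: "LOW"}

    def test_equal_means_stable_tiebreak(self):
        X = np.full((6, 9), 50.0)
        labels = np.repeat([0, 1, 2], 2)
        names = label_profiles(X, labels)
        assert names == {0: "HIGH", 1: "MID", 2: "LOW"}

    def test_rank_names_beyond_three(self):
        X = np.vstack([np.full((2, 9), v) for v in (80.0, 60.0, 40.0, 20.0)])
        labels = np.repeat([0, 1, 2, 3], 2)
        names = label_profiles(X, labels)
        assert names == {0: "R1", 1: "R2", 2: "R3", 3: "R4"}


def _planted_learning_matrix(seed):
    cohort = sample_cohort(54, seed=seed)
    study = simulate_study(cohort, seed=seed, with_traces=False)
    L = learning_matrix_from_truth(study.truth)
    truth = pd.Series(
        {s.subject_id: s.latent_profile.value for s in cohort}
    ).loc[L.index]
    return L, truth


class TestPlantedRecovery:
    def test_three_profiles_recovered(self):
        """Default planted profiles recovered with ARI >= 0.8 in >=90% of seeds."""
        good = 0
        seeds = range(20)
        for seed in seeds:
            L, truth = _planted_learning_matrix(seed)
            tree = complete_linkage(sq_euclidean_matrix(L.to_numpy()))
            ari = adjusted_rand_score(truth, cut_tree(tree, 3))
            good += ari >= 0.8
        assert good / len(seeds) >= 0.9


class TestCompareProfiles:
    def _scored(self, rng, n=54, shift=0.0):
        prof = rng.choice(["LOW", "MID", "HIGH"], size=n, p=[0.46, 0.28, 0.26])
        base = {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": rng.normal(48, 10, n),
        }
        means = {"LOW": 20.0, "MID": 20.0 + shift, "HIGH": 20.0 + shift}
        for m in ("pcl_total", "pcl_cluster_b", "pcl_cluster_c",
                  "pcl_cluster_d", "pcl_cluster_e", "phq_total", "ambi_total"):
            base[m] = np.array([rng.normal(means[p], 10) for p in prof])
        for f in ("ptsd_positive", "mdd_aggregate_positive", "bi_positive"):
            base[f] = rng.uniform(size=n) < 0.4
        scored = pd.DataFrame(base)
        profiles = pd.Series(prof, index=scored["subject_id"], name="profile")
        return scored, profiles

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        sig = 0
        reps = 100
        for _ in range(reps):
            scored, profiles = self._scored(rng)
            rep = compare_profiles(profiles, scored)
            sig += rep["anova"]["pcl_total"]["p"] < 0.05
        assert sig / reps <= 0.10  # nominal false-positive rate

    def test_planted_separation_detected(self):
        """A published-size Low-vs-rest separation drives the first Helmert
        contrast significant in most replicates."""
        rng = np.random.default_rng(9)
        hits = 0
        reps = 50
        for _ in range(reps):
            scored, profiles = self._scored(rng, shift=17.0)  # Table-2-like gap
            rep = compare_profiles(profiles, scored)
            c1 = rep["helmert"]["pcl_total"][0]
            hits += c1["p"] < 0.05
        assert hits / reps >= 0.8

    def test_proportions_sum_per_flag(self):
        rng = np.random.default_rng(10)
        scored, profiles = self._scored(rng)
        rep = compare_profiles(profiles, scored)
        for flag, props in rep["proportions"].items():
            assert set(props) == {"LOW", "MID", "HIGH"}
            for v in props.values():
                assert 0.0 <= v <= 1.0
        assert sum(rep["profile_share"].values()) == pytest.approx(1.0)


def test_run_subtype_week2_forces_three_groups():
    L, _ = _planted_learning_matrix(0)
    sol, _ = run_subtype(L, None, "week2")
    assert sol.k == 3
    assert set(sol.profile_names.values()) == {"HIGH", "MID", "LOW"}
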