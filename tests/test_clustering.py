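"""Cosine distance, Ward dendrograms, silhouette-based k selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pancanstrat import cosine_distance, cut_clusters, find_k, to_newick, ward_tree
from pancanstrat.exceptions import ZeroVectorError


def blobs(rng, centers, per_blob=10, sd=0.05):
    rows, labels = [], []
    for i, center in enumerate(centers):
        for _ in range(per_blob):
            rows.append(np.asarray(center, dtype=float) + rng.normal(0, sd, len(center)))
            labels.append(i)
    ids = [f"S{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids), pd.Series(labels, index=ids)


def brute_force_mean_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Hand-computed silhouette definition: s = (b - a) / max(a, b); singletons 0."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def brute_force_ward_d2(d: np.ndarray):
    """Naive Lance-Williams Ward agglomeration on squared distances (oracle)."""
    n = d.shape[0]
    d2 = d.astype(float) ** 2
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = len(active[i]), len(active[j])
        merges.append((min(i, j), max(i, j), np.sqrt(best), si + sj))
        members = active.pop(i) + active.pop(j)
        new = {}
        for k in active:
            sk = len(active[k])
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dij = best
            lw = ((si + sk) * dik + (sj + sk) * djk - sk * dij) / (si + sj + sk)
            new[tuple(sorted((next_id, k)))] = lw
        dist = {
            pair: v
            for pair, v in dist.items()
            if i not in pair and j not in pair
        }
        dist.update(new)
        active[next_id] = members
        next_id += 1
    return merges


class TestCosineDistance:
    def test_identical_vectors_distance_zero(self):
        profiles = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["S1", "S2"])
        d = cosine_distance(profiles)
        assert d.loc["S1", "S2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_45_degrees(self):
        profiles = pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=["S1", "S2"])
        d = cosine_distance(profiles)
        assert d.loc["S1", "S2"] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_orthogonal_vectors_distance_one(self):
        profiles = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["S1", "S2"])
        assert cosine_distance(profiles).loc["S1", "S2"] == pytest.approx(1.0)

    def test_opposed_log_ratio_vectors_exceed_one(self):
        profiles = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["S1", "S2"])
        assert cosine_distance(profiles).loc["S1", "S2"] == pytest.approx(2.0)

    def test_zero_norm_vector_error_names_sample(self):
        profiles = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["S1", "DEAD"])
        with pytest.raises(ZeroVectorError, match="DEAD"):
            cosine_distance(profiles)


class TestWardTree:
    def test_two_samples_single_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["S1", "S2"], columns=["S1", "S2"])
        tree = ward_tree(d)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.4)

    def test_matches_naive_ward_recomputation(self, rng):
        points = rng.normal(size=(7, 3))
        from scipy.spatial.distance import squareform, pdist

        d_arr = squareform(pdist(points))
        ids = [f"S{i}" for i in range(7)]
        tree = ward_tree(pd.DataFrame(d_arr, index=ids, columns=ids))
        oracle = brute_force_ward_d2(d_arr)
        np.testing.assert_allclose(tree.merges[:, 2], [m[2] for m in oracle], rtol=1e-10)
        np.testing.assert_allclose(tree.merges[:, 3], [m[3] for m in oracle])

    def test_final_merge_joins_two_tight_triplets(self, rng):
        profiles, _ = blobs(rng, [(1, 0, 0), (0, 0, 1)], per_blob=3)
        d = cosine_distance(profiles)
        tree = ward_tree(d)
        assignment = cut_clusters(tree, 2)
        assert assignment.members(1) == ["S0", "S1", "S2"]
        assert assignment.members(2) == ["S3", "S4", "S5"]

    def test_sample_order_permutation_gives_same_partitions(self, rng):
        profiles, _ = blobs(rng, [(1, 0), (0, 1), (1, 1)], per_blob=4, sd=0.02)
        d1 = cosine_distance(profiles)
        perm = rng.permutation(len(profiles))
        d2 = cosine_distance(profiles.iloc[perm])
        t1, t2 = ward_tree(d1), ward_tree(d2)
        for k in (2, 3, 4):
            c1 = cut_clusters(t1, k).labels
            c2 = cut_clusters(t2, k).labels
            assert adjusted_rand_score(c1[c2.index], c2) == pytest.approx(1.0)

    def test_fewer_than_two_samples_is_error(self):
        d = pd.DataFrame([[0.0]], index=["S1"], columns=["S1"])
        with pytest.raises(ValueError):
            ward_tree(d)


class TestCutClusters:
    def test_k_one_is_single_cluster(self, rng):
        profiles, _ = blobs(rng, [(1, 0), (0, 1)], per_blob=3)
        tree = ward_tree(cosine_distance(profiles))
        assignment = cut_clusters(tree, 1)
        assert assignment.k == 1 and set(assignment.labels) == {1}

    def test_k_equals_n_is_all_singletons(self, rng):
        profiles, _ = blobs(rng, [(1, 0), (0, 1)], per_blob=2)
        tree = ward_tree(cosine_distance(profiles))
        assignment = cut_clusters(tree, 4)
        assert sorted(assignment.labels) == [1, 2, 3, 4]

    def test_planted_three_clusters_recovered(self, rng):
        profiles, truth = blobs(rng, [(1, 0, 0), (0, 1, 0), (0, 0, 1)], per_blob=8)
        tree = ward_tree(cosine_distance(profiles))
        assignment = cut_clusters(tree, 3)
        assert adjusted_rand_score(truth, assignment.labels) == pytest.approx(1.0)

    def test_cluster_indices_ordered_by_first_appearance(self, rng):
        profiles, _ = blobs(rng, [(1, 0), (0, 1)], per_blob=3)
        tree = ward_tree(cosine_distance(profiles))
        labels = cut_clusters(tree, 2).labels
        assert labels.iloc[0] == 1  # first sample always opens cluster 1

    def test_k_out_of_range_is_error(self, rng):
        profiles, _ = blobs(rng, [(1, 0)], per_blob=3)
        tree = ward_tree(cosine_distance(profiles))
        with pytest.raises(ValueError):
            cut_clusters(tree, 5)


class TestFindK:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_recovers_planted_blob_count(self, rng, n_blobs):
        centers = [(1, 0, 0), (0, 1, 0), (0, 0, 1)][:n_blobs]
        profiles, _ = blobs(rng, centers, per_blob=10)
        d = cosine_distance(profiles)
        tree = ward_tree(d)
        k, sweep = find_k(d, tree, k_max=6)
        assert k == n_blobs

    def test_sweep_matches_brute_force_silhouette(self, rng):
        profiles, _ = blobs(rng, [(1, 0, 0), (0, 1, 0), (0, 0, 1)], per_blob=6, sd=0.2)
        d = cosine_distance(profiles)
        tree = ward_tree(d)
        _, sweep = find_k(d, tree, k_max=5)
        for k in sweep.index:
            labels = cut_clusters(tree, k).labels.to_numpy()
            expected = brute_force_mean_silhouette(d.to_numpy(), labels)
            assert sweep[k] == pytest.approx(expected, abs=1e-12)

    def test_k_max_two_returns_two(self, rng):
        profiles, _ = blobs(rng, [(1, 0, 0), (0, 1, 0), (0, 0, 1)], per_blob=4)
        d = cosine_distance(profiles)
        k, _ = find_k(d, ward_tree(d), k_max=2)
        assert k == 2

    def test_identical_samples_is_error(self):
        profiles = pd.DataFrame(np.ones((5, 3)), index=[f"S{i}" for i in range(5)])
        d = cosine_distance(profiles)
        with pytest.raises(ValueError, match="identical"):
            find_k(d, ward_tree(d), k_max=3)

    def test_silhouettes_lie_in_unit_interval(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(15, 4)),
                                index=[f"S{i}" for i in range(15)])
        d = cosine_distance(profiles)
        _, sweep = find_k(d, ward_tree(d), k_max=8)
        valid = sweep.dropna()
        assert ((valid >= -1) & (valid <= 1)).all()


def test_newick_export_contains_all_leaves(rng):
    profiles, _ = blobs(rng, [(1, 0), (0, 1)], per_blob=3)
    tree = ward_tree(cosine_distance(profiles))
    nwk = to_newick(tree)
    assert nwk.endswith(";")
    for sid in profiles.index:
        assert sid in nwk
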