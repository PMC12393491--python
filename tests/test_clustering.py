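import itertools

import numpy as np
import pandas as pd
import pytest

from capdyn.clustering import (
    ClusterSolution,
    _CorrDistance,
    correlation_distance,
    explained_variance,
    k_scan_ceiling,
    kmedoids,
    map_state_to_networks,
    match_states,
    medoid_silhouette,
    scan_k,
    select_k,
    split_half_stability,
    state_absence_fraction,
)
from capdyn.datatypes import ParcellationTable, ValidationError
from capdyn.synthetic import (
    default_network_partition,
    emit_bold,
    generate_state_patterns,
    simulate_state_sequence,
)

from _oracles import brute_force_kmedoids, pairwise_correlation_distances


class TestCorrelationDistance:
    def test_identical_and_flipped(self):
        v = np.array([1.0, -2.0, 3.0, 0.5])
        assert correlation_distance(v, v) == pytest.approx(0.0, abs=1e-12)
        assert correlation_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_value(self):
        # r = 6.5 / sqrt(5 * 8.75) = 0.98270 -> d = 0.01730
        d = correlation_distance([1, 2, 3, 4], [1, 2, 3, 5])
        assert d == pytest.approx(0.017297, abs=1e-5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_provider_matches_direct_definition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 15))
        dist = _CorrDistance(x)
        d = dist.rows(np.arange(15))
        np.testing.assert_allclose(
            d, pairwise_correlation_distances(x), atol=1e-10
        )


class TestKMedoids:
    def test_separable_planted_labels_recovered(self):
        centroids = generate_state_patterns(2, 20, seed=0)
        labels = simulate_state_sequence(np.full((2, 2), 0.5), 60, seed=1)
        ts = emit_bold(labels, centroids, noise_sd=1e-4, seed=2)
        sol = kmedoids(ts.matrix, 2, n_restarts=3, seed=0)
        match = match_states(sol.mean_centroids, centroids)
        remapped = match.permutation[sol.labels - 1] + 1
        assert np.array_equal(remapped, labels)

    @pytest.mark.parametrize("k,t,trial", [(2, 10, 0), (2, 10, 1), (3, 12, 2),
                                           (3, 12, 3), (2, 12, 4)])
    def test_matches_exhaustive_optimum_on_toys(self, k, t, trial):
        rng = np.random.default_rng(trial)
        x = rng.normal(size=(6, t))
        sol = kmedoids(x, k, n_restarts=5, seed=trial)
        d = pairwise_correlation_distances(x)
        assert sol.total_within_distance == pytest.approx(
            brute_force_kmedoids(d, k), abs=1e-9
        )

    def test_objective_monotone_descent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 200))
        sol = kmedoids(x, 4, n_restarts=2, seed=0)
        hist = np.asarray(sol.objective_history)
        assert np.all(np.diff(hist) <= 1e-8)

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 120))
        sol = kmedoids(x, 3, n_restarts=2, seed=0)
        for c, m in enumerate(sol.medoid_frame_indices):
            assert sol.labels[m] == c + 1
        assert set(sol.labels) == {1, 2, 3}

    def test_frame_order_invariance(self):
        centroids = generate_state_patterns(3, 24, seed=1)
        labels = simulate_state_sequence(np.full((3, 3), 1 / 3), 90, seed=2)
        x = emit_bold(labels, centroids, noise_sd=0.3, seed=3).matrix
        rng = np.random.default_rng(7)
        perm = rng.permutation(x.shape[1])
        sol = kmedoids(x, 3, n_restarts=1, seed=0)  # deterministic BUILD init
        sol_p = kmedoids(x[:, perm], 3, n_restarts=1, seed=0)
        assert sol.total_within_distance == pytest.approx(
            sol_p.total_within_distance, abs=1e-9
        )
        assert set(perm[sol_p.medoid_frame_indices]) == set(
            sol.medoid_frame_indices
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(6, 80))
        a = kmedoids(x, 3, n_restarts=4, seed=9)
        b = kmedoids(x, 3, n_restarts=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(
            a.medoid_frame_indices, b.medoid_frame_indices
        )

    def test_invalid_k_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ValidationError):
            kmedoids(x, 1)
        with pytest.raises(ValidationError):
            kmedoids(x, 10)


def _manual_solution(x, medoids):
    d = pairwise_correlation_distances(x)
    dm = d[medoids]
    labels = dm.argmin(axis=0) + 1
    k = len(medoids)
    centroids = np.stack([x[:, labels == c + 1].mean(axis=1) for c in range(k)])
    return ClusterSolution(
        k=k, medoid_frame_indices=np.asarray(medoids), labels=labels,
        mean_centroids=centroids,
        total_within_distance=float(dm.min(axis=0).sum()), restart_seed=0,
    )


class TestExplainedVariance:
    def test_k1_is_zero_and_kT_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 8))
        d = pairwise_correlation_distances(x)
        grand = int(np.argmin((d**2).sum(axis=1)))
        sol1 = ClusterSolution(
            k=1, medoid_frame_indices=np.array([grand]),
            labels=np.ones(8, dtype=int),
            mean_centroids=x.mean(axis=1, keepdims=True).T,
            total_within_distance=float(d[grand].sum()), restart_seed=0,
        )
        assert explained_variance(x, sol1) == pytest.approx(0.0, abs=1e-12)
        sol_t = ClusterSolution(
            k=8, medoid_frame_indices=np.arange(8),
            labels=np.arange(1, 9), mean_centroids=x.T,
            total_within_distance=0.0, restart_seed=0,
        )
        assert explained_variance(x, sol_t) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_sums(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 6))
        sol = _manual_solution(x, [0, 3])
        d = pairwise_correlation_distances(x)
        num = sum(
            d[sol.medoid_frame_indices[l - 1], t] ** 2
            for t, l in enumerate(sol.labels)
        )
        den = min((d**2).sum(axis=1))
        assert explained_variance(x, sol) == pytest.approx(1 - num / den, abs=1e-12)


class TestMedoidSilhouette:
    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 12))
        sol = kmedoids(x, 3, n_restarts=2, seed=0)
        d = pairwise_correlation_distances(x)
        dm = d[sol.medoid_frame_indices]
        expected = []
        for t in range(12):
            ds = np.sort(dm[:, t])
            d1, d2 = ds[0], ds[1]
            expected.append(0.0 if max(d1, d2) == 0 else (d2 - d1) / max(d1, d2))
        values, mean = medoid_silhouette(x, sol)
        np.testing.assert_allclose(values, expected, atol=1e-9)
        assert mean == pytest.approx(np.mean(expected), abs=1e-9)

    def test_coincident_medoid_limit(self):
        # a frame sitting on its medoid scores -> 1 as d2 grows
        x = np.array([
            [1.0, 1.0, -1.0, 0.2],
            [0.0, 0.0, 0.5, 1.0],
            [-1.0, -1.0, 1.0, -0.5],
            [0.5, 0.5, -0.2, 0.3],
        ])
        sol = _manual_solution(x, [0, 2])
        values, _ = medoid_silhouette(x, sol)
        assert values[1] > 0.95  # duplicate of medoid 0, far from medoid 1


class TestStateAbsence:
    def test_counting(self):
        labels = np.array([1, 2, 1, 2, 1, 2, 1, 1])
        sol = ClusterSolution(
            k=2, medoid_frame_indices=np.array([0, 1]), labels=labels,
            mean_centroids=np.zeros((2, 3)), total_within_distance=0.0,
            restart_seed=0,
        )
        subjects = np.repeat(["a", "b", "c", "d"], 2)
        assert state_absence_fraction(sol, subjects) == pytest.approx(0.25)
        sol_all = ClusterSolution(
            k=2, medoid_frame_indices=np.array([0, 1]),
            labels=np.array([1, 2] * 4), mean_centroids=np.zeros((2, 3)),
            total_within_distance=0.0, restart_seed=0,
        )
        assert state_absence_fraction(sol_all, subjects) == 0.0


class TestSelectK:
    def test_scan_ceiling_for_ten_minute_tr21_scan(self):
        assert k_scan_ceiling(600.0, 2.1) == 17

    def test_recovers_planted_k(self, small_dataset):
        report = scan_k(small_dataset, k_min=2, k_max=6, n_restarts=4, seed=0)
        ev = report.table["explained_variance"].to_numpy()
        assert np.all(np.diff(ev) >= -1e-6)  # nondecreasing in k
        selection = select_k(report)
        assert selection.conclusive
        assert selection.k == 4

    def test_absence_rises_beyond_planted_k(self, small_dataset):
        report = scan_k(small_dataset, k_min=2, k_max=6, n_restarts=4, seed=0)
        t = report.table.set_index("k")
        assert (
            t.loc[6, "state_absence_fraction"]
            >= t.loc[4, "state_absence_fraction"]
        )

    def test_single_state_data_non_conclusive(self):
        rng = np.random.default_rng(4)
        pattern = rng.normal(size=(12, 1))
        x = pattern + 0.05 * rng.normal(size=(12, 240))
        from capdyn.datatypes import ConcatenatedDataset
        ds = ConcatenatedDataset(
            matrix=x,
            frame_subject_index=np.repeat([f"s{i}" for i in range(4)], 60),
            subject_boundaries=np.array([60, 120, 180]),
            roi_labels=[f"r{i}" for i in range(12)],
            tr_by_subject={f"s{i}": 2.0 for i in range(4)},
        )
        report = scan_k(ds, k_min=2, k_max=4, n_restarts=2, seed=0)
        selection = select_k(report)
        assert not selection.conclusive


class TestMatchStates:
    def test_recovers_shuffle(self):
        c = generate_state_patterns(4, 40, seed=0)
        perm = np.array([2, 0, 3, 1])
        match = match_states(c, c[perm])
        # matched partner of state i is where i landed in the shuffle
        np.testing.assert_array_equal(perm[match.permutation], np.arange(4))
        np.testing.assert_allclose(match.matched_correlations, 1.0, atol=1e-12)

    def test_assignment_beats_greedy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=(4, 30))
            b = rng.normal(size=(4, 30))
            match = match_states(a, b)
            corr = np.corrcoef(a, b)[:4, 4:]
            best = max(
                sum(corr[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert match.matched_correlations.sum() == pytest.approx(best, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            match_states(np.zeros((2, 5)), np.zeros((3, 5)))


class TestSplitHalf:
    def test_structured_data_is_stable(self, small_dataset):
        corrs = split_half_stability(small_dataset, k=4, n_splits=3, seed=0,
                                     n_restarts=2)
        assert corrs.shape == (3, 4)
        assert np.median(corrs) > 0.9

    def test_noise_less_stable_than_structure(self, small_dataset):
        rng = np.random.default_rng(6)
        noise = rng.normal(size=(20, 400))
        noise_corrs = split_half_stability(noise, k=4, n_splits=3, seed=0,
                                           n_restarts=2)
        struct_corrs = split_half_stability(small_dataset, k=4, n_splits=3,
                                            seed=0, n_restarts=2)
        assert np.median(struct_corrs) > np.median(noise_corrs)


class TestNetworkMapping:
    def _parcellation(self, n=40):
        part = default_network_partition(n)
        return ParcellationTable(pd.DataFrame({
            "roi_label": [f"roi{i:03d}" for i in range(n)],
            "network": part,
        })), part

    def test_single_network_activation(self):
        parc, part = self._parcellation()
        x = np.where(part == "VIS", 1.0, 0.0)
        profile = map_state_to_networks(x, parc).set_index("network")
        assert profile.loc["VIS", "positive"] == pytest.approx(1.0)
        assert profile.drop("VIS")["positive"].abs().max() == 0.0
        assert profile["negative"].abs().max() == 0.0

    def test_sign_flip_swaps_profiles(self):
        parc, _ = self._parcellation()
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        p1 = map_state_to_networks(x, parc)
        p2 = map_state_to_networks(-x, parc)
        np.testing.assert_allclose(p1["positive"], p2["negative"], atol=1e-12)
        np.testing.assert_allclose(p1["negative"], p2["positive"], atol=1e-12)

    def test_planted_state_maps_to_designed_networks(self):
        from capdyn.synthetic import DEFAULT_STATE_DESIGN
        parc, part = self._parcellation(85)
        centroids = generate_state_patterns(4, 85, part)
        for s, (pos_nets, neg_nets) in enumerate(DEFAULT_STATE_DESIGN):
            profile = map_state_to_networks(centroids[s], parc).set_index("network")
            top_pos = profile["positive"].idxmax()
            top_neg = profile["negative"].idxmax()
            assert top_pos in pos_nets
            assert top_neg in neg_nets
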