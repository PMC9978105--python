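import numpy as np
import pytest

from erpdtw import (SSEAverager, build_distance_matrix,
                    compute_group_distances, config_for_scale, epoch_distance,
                    generate_dataset, group_trials, similar_group, sse_average)


class TestGroupTrials:
    def test_partition_covers_every_trial_once(self, small_dataset):
        groups = group_trials(small_dataset)
        assert len(groups) == 4                      # 2 subjects x 2 labels
        all_idx = np.concatenate(list(groups.values()))
        assert sorted(all_idx) == list(range(len(small_dataset)))
        for (subj, label), idx in groups.items():
            assert np.all(small_dataset.subject_ids[idx] == subj)
            assert np.all(small_dataset.labels[idx] == label)

    def test_missing_condition_emits_no_group(self, small_dataset):
        only_related = small_dataset.select(small_dataset.labels == "Related")
        groups = group_trials(only_related)
        assert all(label == "Related" for _, label in groups)

    def test_empty_dataset_empty_map(self, small_dataset):
        assert group_trials(small_dataset.select([])) == {}

    def test_keys_sorted(self, small_dataset):
        keys = list(group_trials(small_dataset))
        assert keys == sorted(keys)


class TestDistanceMatrix:
    def test_single_trial_group(self, rng):
        dm = build_distance_matrix(rng.standard_normal((1, 8, 2)))
        assert dm.tolist() == [[0.0]]

    def test_symmetric_zero_diagonal_matches_pairwise(self, rng):
        epochs = rng.standard_normal((4, 8, 3))
        dm = build_distance_matrix(epochs)
        assert np.array_equal(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        for i in range(4):
            for j in range(i + 1, 4):
                assert dm[i, j] == pytest.approx(
                    epoch_distance(epochs[i], epochs[j]))

    def test_cache_round_trip(self, small_dataset, tmp_path):
        first = compute_group_distances(small_dataset, cache_dir=tmp_path)
        assert (tmp_path / "index.json").exists()
        second = compute_group_distances(small_dataset, cache_dir=tmp_path)
        for key in first:
            assert np.array_equal(first[key], second[key])


class TestSimilarGroup:
    dm = np.array([[0.0, 2.0, 1.0, 3.0],
                   [2.0, 0.0, 2.0, 1.0],
                   [1.0, 2.0, 0.0, 2.0],
                   [3.0, 1.0, 2.0, 0.0]])

    def test_n_one_is_anchor_alone(self):
        assert similar_group(self.dm, 2, 1).tolist() == [2]

    def test_full_group_when_n_reaches_size(self):
        assert similar_group(self.dm, 0, 4).tolist() == [0, 1, 2, 3]
        assert similar_group(self.dm, 0, 99).tolist() == [0, 1, 2, 3]

    def test_nearest_selection(self):
        assert similar_group(self.dm, 0, 2).tolist() == [0, 2]
        assert similar_group(self.dm, 1, 2).tolist() == [1, 3]

    def test_tie_breaks_by_lower_index(self):
        # anchor 0: trials 1 and 2 tie at distance 2 -> lower index wins
        dm = np.array([[0.0, 2.0, 2.0], [2.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        assert similar_group(dm, 0, 2).tolist() == [0, 1]

    def test_anchor_out_of_range(self):
        with pytest.raises(IndexError):
            similar_group(self.dm, 7, 2)


@pytest.fixture(scope="module")
def averaged_pair():
    """Small dataset plus its SSE average (N=3), shared across tests."""
    ds = generate_dataset(config_for_scale(
        seq_len=16, n_channels=3, n_subjects=2, trials_per_label=4, seed=7))
    return ds, sse_average(ds, n_similar=3, gamma=1.0, max_iter=15)


class TestSseAverage:
    def test_identity_at_n_one(self, small_dataset):
        out = sse_average(small_dataset, n_similar=1)
        assert out.equals(small_dataset)
        assert out.data is not small_dataset.data

    def test_shapes_and_metadata_preserved(self, averaged_pair):
        ds, out = averaged_pair
        assert out.data.shape == ds.data.shape
        assert np.array_equal(out.subject_ids, ds.subject_ids)
        assert np.array_equal(out.labels, ds.labels)
        assert np.array_equal(out.trial_ids, ds.trial_ids)
        assert out.channel_names == ds.channel_names
        assert not np.allclose(out.data, ds.data)    # it did average

    def test_subject_isolation(self, averaged_pair):
        # dropping the other subject leaves this subject's outputs unchanged
        ds, out = averaged_pair
        keep = ds.subject_ids == "S00"
        out_solo = sse_average(ds.select(keep), n_similar=3, gamma=1.0,
                               max_iter=15)
        np.testing.assert_allclose(out_solo.data, out.data[keep], rtol=1e-12)

    def test_channel_independence(self, averaged_pair):
        # perturbing one channel of non-anchor trials changes only that
        # channel of the output (similar groups frozen via shared distance
        # matrices, since neighbour selection sums over channels by design)
        ds, _ = averaged_pair
        dms = compute_group_distances(ds)
        out = sse_average(ds, n_similar=3, gamma=1.0, max_iter=15,
                          distance_matrices=dms)
        perturbed = ds.copy()
        perturbed.data[1:, :, 2] += 0.25
        out_pert = sse_average(perturbed, n_similar=3, gamma=1.0, max_iter=15,
                               distance_matrices=dms)
        np.testing.assert_allclose(out_pert.data[0, :, :2], out.data[0, :, :2],
                                   rtol=1e-12)
        assert not np.allclose(out_pert.data[0, :, 2], out.data[0, :, 2])

    def test_class_separation_not_reduced_vs_arithmetic(self):
        """SSE averaging keeps the Related-vs-Unrelated window separation at
        least as large as arithmetic averaging of the same similar groups."""
        from erpdtw.sse import group_trials, similar_group
        from erpdtw.sse import compute_group_distances

        cfg = config_for_scale(seq_len=32, n_channels=4, n_subjects=2,
                               trials_per_label=8, seed=21)
        ds = generate_dataset(cfg)
        n_sim = 4
        dms = compute_group_distances(ds)
        arith = ds.copy()
        for key, idx in group_trials(ds).items():
            for local, trial in enumerate(idx):
                members = idx[similar_group(dms[key], local, n_sim)]
                arith.data[trial] = ds.data[members].mean(axis=0)
        sse_out = sse_average(ds, n_similar=n_sim, gamma=1.0, max_iter=20,
                              distance_matrices=dms)

        # 300-500 ms window; strongest-topography channel
        lo, hi = int(0.3 * cfg.sfreq), int(0.5 * cfg.sfreq)
        ch = 2   # near the topography peak for the generic montage
        def separation(d):
            rel = d.data[d.labels == "Related", lo:hi, ch].mean()
            unr = d.data[d.labels == "Unrelated", lo:hi, ch].mean()
            return abs(rel - unr)
        assert separation(sse_out) >= separation(arith)

    def test_invalid_params_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sse_average(small_dataset, n_similar=0)
        with pytest.raises(ValueError):
            sse_average(small_dataset, n_similar=2, gamma=0.0)


class TestSSEAveragerEstimator:
    def test_fit_transform_matches_function(self, small_dataset):
        est = SSEAverager(n_similar=3, gamma=1.0, max_iter=15)
        Xt = est.fit_transform(small_dataset.data,
                               y=small_dataset.labels,
                               groups=small_dataset.subject_ids)
        ref = sse_average(small_dataset, n_similar=3, gamma=1.0, max_iter=15)
        np.testing.assert_allclose(Xt, ref.data, rtol=1e-12)

    def test_requires_labels_and_groups(self, small_dataset):
        with pytest.raises(ValueError, match="requires"):
            SSEAverager(n_similar=2).fit_transform(small_dataset.data)

    def test_get_set_params_round_trip(self):
        est = SSEAverager(n_similar=5, gamma=0.5)
        params = est.get_params()
        assert params["n_similar"] == 5
        est.set_params(gamma=2.0)
        assert est.gamma == 2.0
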