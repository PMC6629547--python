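import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.svm import SVC

from voxelreuse import (
    DecodingResult,
    FoldScheme,
    SimulationConfig,
    cluster_extent_threshold,
    cross_generalize,
    cross_validate,
    generate_dataset,
    group_test_vs_chance,
    leave_one_block_out,
    searchlight_map,
    sphere_neighbors,
    train_lsvm,
)
from voxelreuse.decoding import SingleClassError
from voxelreuse.io import ROIMask
from voxelreuse.permutation import permute_condition_labels


def _affine(vs=3.0):
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = vs
    return aff


class TestTrainLsvm:
    def test_separable_one_voxel_problem(self):
        model = train_lsvm(np.array([[-1.0], [1.0]]), np.array([1, 2]))
        pred = model.decision(np.array([[-1.0], [1.0]])) >= 0
        assert list(pred) == [False, True]  # class 2 on the positive side

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            train_lsvm(np.array([[0.0], [1.0]]), np.array([1, 1]))

    def test_xor_is_not_linearly_separable(self):
        """No linear boundary classifies more than 3 of the 4 XOR points."""
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, 2, 2])
        model = train_lsvm(X, y, C=100.0)
        correct = np.sum((model.decision(X) >= 0) == (y == 2))
        assert correct <= 3


class TestFoldScheme:
    def test_overlapping_fold_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldScheme(folds=[(np.array([0, 1]), np.array([1, 2]))])

    def test_duplicate_test_sample_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            FoldScheme(folds=[(np.array([1]), np.array([0])),
                              (np.array([1]), np.array([0]))])

    def test_leave_one_block_out_partitions_all_samples(self):
        scheme = leave_one_block_out(np.repeat(np.arange(1, 9), 2))
        assert scheme.n_folds == 8
        assert all(len(test) == 2 and len(train) == 14 for train, test in scheme.folds)


class TestCrossValidate:
    def test_noiseless_planted_effect_decodes_perfectly(self, make_dataset):
        (ps,), _ = make_dataset(noise_sd=0.0, effect_size=2.0)
        for task in (1, 2):
            assert cross_validate(ps, task=task) == 100.0

    def test_matches_brute_force_per_fold_loop(self, make_dataset):
        """Pooled CV accuracy equals an explicit sklearn train/predict loop."""
        (ps,), _ = make_dataset(effect_size=1.0, seed=21)
        sel = ps.select(task=1, relevance="relevant")
        y = sel.labels["condition"].to_numpy()
        blocks = sel.labels["block"].to_numpy()
        correct, total = 0, 0
        for b in np.unique(blocks):
            tr, te = blocks != b, blocks == b
            clf = SVC(kernel="linear", C=1.0).fit(sel.data[tr], y[tr])
            correct += int(np.sum(clf.predict(sel.data[te]) == y[te]))
            total += int(te.sum())
        assert cross_validate(ps, task=1) == 100.0 * correct / total

    def test_accuracy_invariant_to_voxel_reordering(self, make_dataset, rng):
        (ps,), _ = make_dataset(effect_size=1.0, seed=33)
        baseline = cross_validate(ps, task=1)
        perm = rng.permutation(ps.n_voxels)
        ps.data = ps.data[:, perm]
        assert cross_validate(ps, task=1) == baseline

    def test_block_permuted_labels_decode_at_chance(self):
        """Mean CV accuracy under block-wise label permutation sits at 50 %
        (scaled-down version of the 1000-subject check in the acceptance
        suite)."""
        accs = []
        for seed in range(200):
            cfg = SimulationConfig(n_subjects=1, grid_dims=(4, 3, 2), effect_size=1.0,
                                   rng_seed=seed)
            (ps,), _ = generate_dataset(cfg)
            r = np.random.default_rng(seed + 10_000)
            perm = permute_condition_labels(ps, task=1, rng=r, relevance="relevant",
                                            unit="block")
            accs.append(cross_validate(perm, task=1))
        assert np.mean(accs) == pytest.approx(50.0, abs=3.0)


class TestCrossGeneralize:
    def test_identical_patterns_generalize_perfectly(self, make_dataset):
        (ps,), _ = make_dataset(noise_sd=0.0, effect_size=2.0, shared_fraction=1.0)
        res = cross_generalize(ps)
        assert res["1->2"] == res["2->1"] == res["mean"] == 100.0

    def test_mean_is_arithmetic_mean_of_directions(self, make_dataset):
        (ps,), _ = make_dataset(effect_size=1.0, shared_fraction=0.5, seed=8)
        res = cross_generalize(ps)
        assert res["mean"] == pytest.approx((res["1->2"] + res["2->1"]) / 2)

    def test_independent_task_codes_generalize_at_chance(self):
        accs = []
        for seed in range(100):
            cfg = SimulationConfig(n_subjects=1, grid_dims=(4, 3, 2), effect_size=1.5,
                                   shared_fraction=0.0, rng_seed=seed)
            (ps,), _ = generate_dataset(cfg)
            accs.append(cross_generalize(ps)["mean"])
        assert np.mean(accs) == pytest.approx(50.0, abs=4.0)


class TestGroupTest:
    def test_symmetric_jitter_gives_t_zero(self):
        res = group_test_vs_chance({"a": 48.0, "b": 52.0, "c": 46.0, "d": 54.0})
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(0.5)

    def test_zero_variance_flagged_degenerate(self):
        res = group_test_vs_chance({s: 60.0 for s in "abcd"})
        assert res["degenerate"] is True and np.isnan(res["t"])

    def test_hand_computed_t_statistic(self):
        accs = dict(zip("abcde", [52.0, 54.0, 56.0, 58.0, 60.0]))
        res = group_test_vs_chance(DecodingResult(accuracies=accs))
        assert res["mean_accuracy"] == 56.0
        assert res["t"] == pytest.approx(4.2426, abs=1e-3)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_test_vs_chance({"a": 55.0})


class TestSphere:
    def test_radius_zero_is_center_only(self):
        idx = sphere_neighbors((5, 5, 5), _affine(), (2, 2, 2), 0.0)
        assert list(idx) == [np.ravel_multi_index((2, 2, 2), (5, 5, 5))]

    def test_5mm_sphere_on_3mm_grid_has_19_voxels(self):
        """Face neighbours at 3.0 mm and edge neighbours at 4.24 mm are in;
        corner neighbours at 5.20 mm are out: 1 + 6 + 12 = 19."""
        idx = sphere_neighbors((7, 7, 7), _affine(3.0), (3, 3, 3), 5.0)
        assert idx.size == 19

    def test_corner_center_is_clipped_to_grid(self):
        idx = sphere_neighbors((7, 7, 7), _affine(3.0), (0, 0, 0), 5.0)
        # centre + 3 face + 3 edge neighbours survive clipping to the octant
        assert idx.size == 7

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            sphere_neighbors((5, 5, 5), _affine(), (5, 0, 0), 5.0)


class TestSearchlight:
    def test_tiny_radius_equals_single_voxel_decoding(self, make_dataset):
        (ps,), _ = make_dataset(grid_dims=(3, 3, 2), effect_size=1.5, seed=2)
        mask = ROIMask(name="all", volume=np.ones((3, 3, 2), bool), affine=_affine())
        amap = searchlight_map(ps, mask, radius_mm=1.0, task=1)
        for lin in range(ps.n_voxels):
            center = np.unravel_index(lin, (3, 3, 2))
            single = cross_validate(
                type(ps)(subject=ps.subject, data=ps.data[:, [lin]], labels=ps.labels,
                         voxel_coords_mm=ps.voxel_coords_mm[[lin]], roi_name="v",
                         grid_dims=None),
                task=1,
            )
            assert amap.volume[center] == single

    def test_signal_blob_outscores_noise_background(self):
        """Mean searchlight accuracy inside a planted compact blob exceeds
        the pure-noise background (averaged over seeds)."""
        inside, outside = [], []
        grid = (6, 6, 4)
        blob = np.zeros(grid, bool)
        blob[1:3, 1:3, 1:3] = True
        blob_lin = np.flatnonzero(blob.ravel())
        for seed in range(10):
            cfg = SimulationConfig(n_subjects=1, grid_dims=grid, effect_size=0.0,
                                   rng_seed=seed)
            (ps,), _ = generate_dataset(cfg)
            sel_rows = ((ps.labels["task"] == 1)
                        & (ps.labels["relevance"] == "relevant")).to_numpy()
            sign = np.where(ps.labels.loc[sel_rows, "condition"] == 1, 1.0, -1.0)
            ps.data[np.ix_(np.flatnonzero(sel_rows), blob_lin)] += sign[:, None]
            mask = ROIMask(name="all", volume=np.ones(grid, bool), affine=_affine())
            amap = searchlight_map(ps, mask, radius_mm=3.0, task=1)
            inside.append(np.nanmean(amap.volume[blob]))
            outside.append(np.nanmean(amap.volume[~blob]))
        assert np.mean(inside) > np.mean(outside) + 5.0

    def test_all_noise_map_is_at_chance(self):
        cfg = SimulationConfig(n_subjects=1, grid_dims=(6, 6, 4), effect_size=0.0,
                               rng_seed=17)
        (ps,), _ = generate_dataset(cfg)
        mask = ROIMask(name="all", volume=np.ones((6, 6, 4), bool), affine=_affine())
        amap = searchlight_map(ps, mask, radius_mm=3.0, task=1)
        assert np.nanmean(amap.volume) == pytest.approx(50.0, abs=4.0)


class TestClusterThreshold:
    def test_empty_suprathreshold_set(self):
        assert cluster_extent_threshold(np.zeros((5, 5, 5)), 1.0) == []

    def test_single_cube_cluster(self):
        vol = np.zeros((8, 8, 8))
        vol[1:6, 1:6, 1:6] = 5.0
        clusters = cluster_extent_threshold(vol, 1.0, extent=20)
        assert len(clusters) == 1 and clusters[0]["size"] == 125

    def test_corner_touching_cubes_are_separate_under_6_connectivity(self):
        vol = np.zeros((8, 8, 8))
        vol[0:3, 0:3, 0:3] = 2.0
        vol[3:6, 3:6, 3:6] = 3.0  # shares only the corner voxel diagonal
        clusters = cluster_extent_threshold(vol, 1.0, extent=1)
        assert len(clusters) == 2
        assert sorted(c["size"] for c in clusters) == [27, 27]

    def test_extent_filters_small_clusters(self):
        vol = np.zeros((6, 6, 6))
        vol[0, 0, 0:3] = 2.0
        assert cluster_extent_threshold(vol, 1.0, extent=20) == []


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
       st.floats(0.0, 12.0))
def test_sphere_neighbors_matches_exhaustive_distance_check(i, j, k, radius):
    grid, vs = (7, 7, 7), 3.0
    got = set(sphere_neighbors(grid, _affine(vs), (i, j, k), radius))
    expected = set()
    for lin in range(7 * 7 * 7):
        v = np.unravel_index(lin, grid)
        if np.linalg.norm((np.array(v) - (i, j, k)) * vs) <= radius + 1e-9:
            expected.add(lin)
    assert got == expected


def test_standardization_flag_changes_scaling_not_separability(make_dataset):
    """Per-fold z-scoring leaves a noiseless planted effect perfectly
    decodable and is invariant to global rescaling of the data."""
    (ps,), _ = make_dataset(noise_sd=0.0, effect_size=2.0)
    assert cross_validate(ps, task=1, standardize=True) == 100.0
    (ps2,), _ = make_dataset(effect_size=1.0, seed=44)
    base = cross_validate(ps2, task=1, standardize=True)
    ps2.data = ps2.data * 1000.0
    assert cross_validate(ps2, task=1, standardize=True) == base
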