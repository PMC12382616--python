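"""Voxel selection, sparse-PCA refinement, and cluster extraction."""

import numpy as np
import pytest

from rewardmap.cluster import (
    GroupActivation,
    GroupDataMatrix,
    SparsePCAConfig,
    cluster_subject_means,
    connected_components,
    extract_clusters,
    make_toy_label_map,
    select_activated_voxels,
    spca_refine,
)
from rewardmap.exceptions import InvalidInputError, InvalidParameterError
from rewardmap.synthetic import default_phantom, make_phantom

from conftest import flood_fill_components


class TestSelection:
    def test_infinite_threshold_selects_nothing(self):
        rng = np.random.default_rng(0)
        mask = np.ones((6, 6, 3), dtype=bool)
        maps = rng.normal(size=(10, 108))
        with pytest.warns(UserWarning, match="empty"):
            sel = select_activated_voxels(maps, mask, threshold=np.inf)
        assert sel.n_voxels == 0

    def test_noiseless_truth_containment(self):
        """With signal only in one planted cluster and no noise, the
        selected voxel set is exactly that cluster."""
        mask, labels = make_phantom(default_phantom())
        rng = np.random.default_rng(1)
        S = 12
        maps = np.zeros((S, *mask.shape))
        amp = rng.normal(1.0, 0.2, S)
        cluster1 = labels == 1
        maps[:, cluster1] = amp[:, None]
        sel = select_activated_voxels(maps, mask, alpha=0.001)
        assert set(map(tuple, sel.voxel_index)) == \
            set(map(tuple, np.argwhere(cluster1)))
        assert sel.values.shape == (S, cluster1.sum())

    def test_null_selection_rate_matches_alpha(self):
        """Binomial calibration: at alpha=0.001 with 3000 null voxels the
        expected selected count is 3."""
        rng = np.random.default_rng(2)
        mask = np.ones((30, 10, 10), dtype=bool)
        counts = []
        for _ in range(40):
            maps = rng.normal(size=(30, 3000))
            with np.errstate(all="ignore"):
                sel = select_activated_voxels(maps, mask, alpha=0.001)
            counts.append(sel.n_voxels)
        assert np.mean(counts) == pytest.approx(3.0, abs=1.0)

    def test_too_few_subjects_raise(self):
        mask = np.ones((4, 4, 2), dtype=bool)
        with pytest.raises(InvalidInputError):
            select_activated_voxels(np.zeros((1, 32)), mask)


def _planted_group_matrix(rng, n_subjects=40, n_signal=20, n_noise=180,
                          strength=3.0):
    """Two orthogonal signal blocks plus pure-noise columns."""
    f1 = rng.normal(size=n_subjects)
    f2 = rng.normal(size=n_subjects)
    half = n_signal // 2
    X = rng.normal(size=(n_subjects, n_signal + n_noise))
    X[:, :half] += strength * f1[:, None]
    X[:, half:n_signal] += strength * f2[:, None]
    coords = np.column_stack([np.arange(n_signal + n_noise),
                              np.zeros(n_signal + n_noise, dtype=int),
                              np.zeros(n_signal + n_noise, dtype=int)])
    return GroupDataMatrix(values=X, voxel_index=coords), n_signal


class TestSparsePCA:
    def test_zero_penalty_keeps_every_column(self):
        rng = np.random.default_rng(3)
        data, _ = _planted_group_matrix(rng, n_noise=30)
        res = spca_refine(data, SparsePCAConfig(n_components=3, l1_penalty=0.0))
        assert res.kept.all()

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_support_recovery(self, seed):
        """Moderate penalty keeps >=90% of signal columns and <=10% of the
        pure-noise columns, across seeds."""
        rng = np.random.default_rng(seed)
        data, n_signal = _planted_group_matrix(rng)
        res = spca_refine(data, SparsePCAConfig(n_components=2))
        signal_kept = res.kept[:n_signal].mean()
        noise_kept = res.kept[n_signal:].mean()
        assert signal_kept >= 0.9
        assert noise_kept <= 0.1

    def test_support_shrinks_along_penalty_path(self):
        rng = np.random.default_rng(5)
        data, _ = _planted_group_matrix(rng, n_noise=60)
        X = data.values - data.values.mean(axis=0)
        scale = np.abs(X.T @ X).max()
        sizes = []
        for frac in [0.0, 1e-4, 1e-3, 1e-2, 0.05, 0.2, 0.5]:
            res = spca_refine(data, SparsePCAConfig(
                n_components=2, l1_penalty=frac * scale))
            sizes.append(int(res.kept.sum()))
        assert sizes == sorted(sizes, reverse=True)

    def test_components_ordered_by_explained_variance(self):
        rng = np.random.default_rng(6)
        data, _ = _planted_group_matrix(rng)
        res = spca_refine(data, SparsePCAConfig(n_components=3))
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_agrees_with_sklearn_sparse_pca_support(self):
        """Independent check: scikit-learn's SparsePCA concentrates its
        support on the same planted signal columns."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(7)
        data, n_signal = _planted_group_matrix(rng, n_noise=80)
        ours = spca_refine(data, SparsePCAConfig(n_components=2))
        X = data.values - data.values.mean(axis=0)
        ref = sklearn.SparsePCA(n_components=2, alpha=2.0, random_state=0,
                                max_iter=200).fit(X)
        theirs = np.any(ref.components_ != 0, axis=0)
        # both methods retain essentially all planted signal columns
        assert ours.kept[:n_signal].mean() >= 0.9
        assert theirs[:n_signal].mean() >= 0.9
        assert (ours.kept & theirs)[:n_signal].mean() >= 0.9

    def test_small_input_raises(self):
        data = GroupDataMatrix(values=np.zeros((1, 5)),
                               voxel_index=np.zeros((5, 3), dtype=int))
        with pytest.raises(InvalidInputError):
            spca_refine(data)


class TestConnectedComponents:
    def test_face_and_corner_connectivity_semantics(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, 0] = vol[0, 1, 0] = True  # share a face
        _, n = connected_components(vol, 6)
        assert n == 1
        vol2 = np.zeros((4, 4, 4), dtype=bool)
        vol2[0, 0, 0] = vol2[1, 1, 1] = True  # share only a corner
        _, n6 = connected_components(vol2, 6)
        _, n26 = connected_components(vol2, 26)
        assert (n6, n26) == (2, 1)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        vol = rng.random((15, 15, 8)) < 0.2
        labeled, n = connected_components(vol, connectivity)
        ours = {frozenset(map(tuple, np.argwhere(labeled == i)))
                for i in range(1, n + 1)}
        assert ours == flood_fill_components(vol, connectivity)

    def test_invalid_connectivity_raises(self):
        with pytest.raises(InvalidParameterError):
            connected_components(np.zeros((2, 2, 2), dtype=bool), 10)


class TestClusterExtraction:
    def test_subject_means_match_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            maps = rng.normal(size=(rng.integers(2, 12), 6, 6, 3))
            vox = np.unique(rng.integers(0, [6, 6, 3], size=(5, 3)), axis=0)
            out = cluster_subject_means(vox, maps)
            per = np.array([maps[s][tuple(vox.T)].mean()
                            for s in range(maps.shape[0])])
            n = len(per)
            mean = per.sum() / n
            sd = np.sqrt(((per - mean) ** 2).sum() / (n - 1))
            assert np.allclose(out["subject_means"], per, atol=1e-12)
            assert out["mean"] == pytest.approx(mean, abs=1e-12)
            assert out["sd"] == pytest.approx(sd, abs=1e-12)
            assert out["se"] == pytest.approx(sd / np.sqrt(n), abs=1e-12)

    def test_identical_maps_have_zero_sd_se(self):
        maps = np.tile(np.arange(27.0).reshape(3, 3, 3), (5, 1, 1, 1))
        out = cluster_subject_means(np.array([[0, 0, 0], [1, 1, 1]]), maps)
        assert out["sd"] == 0.0 and out["se"] == 0.0

    def test_size_filter_ordering_direction_and_labels(self):
        rng = np.random.default_rng(9)
        dims = (20, 20, 10)
        kept = np.zeros(dims, dtype=bool)
        kept[2:6, 2:6, 2:5] = True     # 48 voxels, positive
        kept[10:16, 10:16, 2:6] = True  # 144 voxels, negative
        kept[18, 18, 8] = True          # singleton, dropped
        maps = rng.normal(0, 0.01, size=(8, *dims))
        maps[:, 2:6, 2:6, 2:5] += 2.0
        maps[:, 10:16, 10:16, 2:6] -= 1.5
        mask = np.ones(dims, dtype=bool)
        label_map, names = make_toy_label_map(mask)
        table = extract_clusters(kept, maps, np.eye(4), connectivity=26,
                                 min_size=20, label_map=label_map,
                                 label_names=names)
        assert len(table) == 2
        assert [c.size for c in table.clusters] == [144, 48]
        assert table.clusters[0].direction == "loss>win"
        assert table.clusters[1].direction == "win>loss"
        assert table.clusters[0].label in names.values()
        # identity affine: world centroid equals the mean voxel coordinate
        assert np.allclose(table.clusters[1].centroid_world,
                           [3.5, 3.5, 3.0])
        frame = table.to_frame()
        assert list(frame.columns) == [
            "id", "size", "label", "direction", "centroid_x", "centroid_y",
            "centroid_z", "mean", "sd", "se"]

    def test_empty_table_allowed(self):
        maps = np.zeros((4, 5, 5, 5))
        table = extract_clusters(np.zeros((5, 5, 5), dtype=bool), maps,
                                 np.eye(4))
        assert len(table) == 0


class TestGroupActivationModel:
    def test_refinement_never_adds_voxels_and_partitions(self):
        rng = np.random.default_rng(10)
        mask, labels = make_phantom(default_phantom())
        S = 16
        maps = rng.normal(0, 1.0, size=(S, *mask.shape))
        maps[:, ~mask] = 0
        for k in range(1, 5):
            maps[:, labels == k] += rng.normal(1.2, 0.3, S)[:, None]
        model = GroupActivation(maps, mask, np.eye(4))
        res = model.fit(min_size=20)
        selected = set(map(tuple, res.selection.voxel_index))
        kept = set(map(tuple, res.selection.voxel_index[res.spca.kept]))
        assert kept <= selected
        clustered = [tuple(v) for c in res.cluster_table.clusters
                     for v in c.voxels]
        assert len(clustered) == len(set(clustered))  # clusters partition
        assert set(clustered) <= kept
        assert "Group activation refinement" in res.summary()

    def test_direction_labels_follow_planted_signs(self):
        rng = np.random.default_rng(11)
        mask, labels = make_phantom(default_phantom())
        S = 16
        maps = rng.normal(0, 0.5, size=(S, *mask.shape))
        maps[:, ~mask] = 0
        signs = [1, 1, -1, -1]
        for k, sign in enumerate(signs, start=1):
            maps[:, labels == k] += sign * rng.normal(1.5, 0.2, S)[:, None]
        res = GroupActivation(maps, mask, np.eye(4)).fit(min_size=20)
        truth_sets = [set(map(tuple, np.argwhere(labels == k)))
                      for k in range(1, 5)]
        for k, sign in enumerate(signs):
            best = max(res.cluster_table.clusters,
                       key=lambda c: len(truth_sets[k] & set(map(tuple, c.voxels))))
            assert best.direction == ("win>loss" if sign > 0 else "loss>win")
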