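import numpy as np
import pytest

from fisseg import nn
from fisseg.keypoints import KeypointCloud
from fisseg.pointseg import (SegTrainConfig, build_seg_model, ce_dice_loss,
                             infer_full_cloud, knn_graph, rigid_augment,
                             AugmentRanges, seg_forward, split_by_label,
                             train_seg, save_checkpoint, load_checkpoint,
                             PointScores)


def brute_force_knn(pts, k):
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :min(k, n - 1)]


class TestKnnGraph:
    @pytest.mark.parametrize("n,k", [(5, 2), (30, 7), (200, 11)])
    def test_matches_brute_force(self, n, k, rng):
        pts = rng.normal(size=(n, 3))
        g = knn_graph(pts, k)
        np.testing.assert_array_equal(g.neighbors, brute_force_knn(pts, k))

    def test_large_n_kdtree_path(self, rng):
        pts = rng.normal(size=(600, 3))
        g = knn_graph(pts, 5)
        oracle = brute_force_knn(pts, 5)
        # same neighbor sets (order may differ only among exact ties)
        assert np.mean([set(a) == set(b)
                        for a, b in zip(g.neighbors, oracle)]) == 1.0

    def test_k_exceeding_n_gives_complete_graph(self, rng):
        pts = rng.normal(size=(6, 3))
        g = knn_graph(pts, 50)
        assert g.k == 5
        for i, row in enumerate(g.neighbors):
            assert set(row) == set(range(6)) - {i}

    def test_duplicate_point_is_nearest_neighbor(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [2, 2, 2]],
                       dtype=float)
        g = knn_graph(pts, 1)
        assert g.neighbors[0, 0] == 2
        assert g.neighbors[2, 0] == 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((1, 3)), 3)


class TestModels:
    @pytest.mark.parametrize("arch", ["pointnet", "dgcnn",
                                      "pointtransformer"])
    def test_forward_shape_and_permutation_equivariance(self, arch, rng):
        model = build_seg_model(arch, seed=0).eval()
        n = 64
        coords = rng.uniform(-1, 1, (n, 3))
        feats = rng.random((n, 125)).astype(np.float32)
        graph = knn_graph(coords, 40) if arch == "dgcnn" else None
        with nn.no_grad():
            out = seg_forward(model, coords, feats, graph).data
        assert out.shape == (n, 4)
        perm = rng.permutation(n)
        pg = knn_graph(coords[perm], 40) if arch == "dgcnn" else None
        with nn.no_grad():
            out_p = seg_forward(model, coords[perm], feats[perm], pg).data
        np.testing.assert_allclose(out_p, out[perm], atol=2e-4)

    def test_pointnet_global_feature_order_invariant(self, rng):
        model = build_seg_model("pointnet", seed=0).eval()
        coords = rng.uniform(-1, 1, (32, 3))
        feats = rng.random((32, 125)).astype(np.float32)
        x = nn.concat([nn.Tensor(coords.astype(np.float32)),
                       nn.Tensor(feats)], axis=-1)
        with nn.no_grad():
            g1 = model.enc(model.local(x)).max(axis=0).data
            perm = rng.permutation(32)
            xp = nn.concat([nn.Tensor(coords[perm].astype(np.float32)),
                            nn.Tensor(feats[perm])], axis=-1)
            g2 = model.enc(model.local(xp)).max(axis=0).data
        np.testing.assert_allclose(g1, g2, atol=1e-5)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            build_seg_model("voxelnet")


class TestCeDiceLoss:
    def test_perfect_prediction_near_zero(self):
        labels = np.array([0, 1, 2, 3, 0, 1])
        logits = nn.Tensor(np.eye(4, dtype=np.float32)[labels] * 40 - 20)
        assert float(ce_dice_loss(logits, labels).data) < 1e-3

    def test_uniform_logits_closed_form(self):
        """Balanced 2-of-4-classes toy with uniform logits: CE = ln 4 and
        the Dice term follows from p_c = 1/4 everywhere."""
        labels = np.array([0, 0, 1, 1])
        logits = nn.Tensor(np.zeros((4, 4), dtype=np.float32))
        loss = float(ce_dice_loss(logits, labels).data)
        delta = 1e-5
        # per present class: dice = (2*(1/4)*2 + d)/(1 + 2 + d); absent: d/(1+d)
        dice_present = (2 * 0.25 * 2 + delta) / (1 + 2 + delta)
        dice_absent = delta / (1 + delta)
        expected = np.log(4) + 1 - (2 * dice_present + 2 * dice_absent) / 4
        assert loss == pytest.approx(expected, rel=1e-4)

    def test_monotone_in_correct_logit(self):
        labels = np.array([1, 1, 0, 2])
        losses = []
        for boost in np.linspace(0, 8, 9):
            logits = np.zeros((4, 4), dtype=np.float32)
            logits[np.arange(4), labels] = boost
            losses.append(float(ce_dice_loss(nn.Tensor(logits), labels).data))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestAugmentation:
    def test_pairwise_distances_scale_uniformly(self, rng):
        coords = rng.uniform(-1, 1, (40, 3))
        out = rigid_augment(coords, 7)
        d0 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        ratio = d1[d0 > 1e-9] / d0[d0 > 1e-9]
        assert ratio.std() < 1e-9
        assert 0.9 - 1e-9 <= ratio.mean() <= 1.1 + 1e-9

    def test_seed_determinism(self, rng):
        coords = rng.uniform(-1, 1, (10, 3))
        np.testing.assert_array_equal(rigid_augment(coords, 3),
                                      rigid_augment(coords, 3))

    def test_zero_ranges_identity(self, rng):
        coords = rng.uniform(-1, 1, (10, 3))
        out = rigid_augment(coords, 0,
                            AugmentRanges(rot_deg=0, translation=0,
                                          scale=(1, 1)))
        np.testing.assert_allclose(out, coords, atol=1e-12)


def _toy_cloud(rng, n=256):
    coords = rng.uniform(-1, 1, (n, 3))
    feats = rng.random((n, 125)).astype(np.float32)
    # separable toy labels: class 1 where x > 0.5
    labels = np.where(coords[:, 0] > 0.5, 1, 0)
    idx = ((coords + 1) / 2 * 15).astype(np.int64)
    return KeypointCloud(coords, idx, feats, "uniform"), labels


class TestTraining:
    def test_smoke_descent_and_reproducibility(self, rng):
        cloud, labels = _toy_cloud(rng)
        cfg = SegTrainConfig(epochs=10, n_points=128, seed=5)
        m1 = build_seg_model("pointnet", seed=2)
        m1, h1 = train_seg(m1, [(cloud, labels)], cfg)
        assert h1[-1] < h1[0]
        m2 = build_seg_model("pointnet", seed=2)
        m2, h2 = train_seg(m2, [(cloud, labels)], cfg)
        np.testing.assert_array_equal(h1, h2)  # bit-for-bit given seeds

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_seg(build_seg_model("pointnet", seed=0), [],
                      SegTrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cloud, labels = _toy_cloud(rng, 64)
        model = build_seg_model("pointnet", seed=1).eval()
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, extra={"note": "test"})
        back, meta = load_checkpoint(path)
        assert meta["arch"] == "pointnet"
        back.eval()
        with nn.no_grad():
            a = seg_forward(model, cloud.coords, cloud.features).data
            b = seg_forward(back, cloud.coords, cloud.features).data
        np.testing.assert_allclose(a, b, atol=1e-7)


class TestInference:
    def test_small_cloud_covered_in_one_round(self, rng):
        cloud, _ = _toy_cloud(rng, 100)
        model = build_seg_model("pointnet", seed=0)
        res = infer_full_cloud(model, cloud, rounds=1, n_points=512, seed=0)
        assert res.coverage.min() >= 1
        assert len(res.labels) == 100

    def test_coverage_first_guarantees_full_coverage(self, rng):
        cloud, _ = _toy_cloud(rng, 700)
        model = build_seg_model("pointnet", seed=0)
        res = infer_full_cloud(model, cloud, rounds=4, n_points=256, seed=0)
        assert res.coverage.min() >= 1
        assert res.scores.shape == (700, 4)
        np.testing.assert_array_equal(res.labels,
                                      np.argmax(res.scores, axis=1))

    def test_empty_cloud_is_na(self):
        from fisseg.keypoints import _empty_cloud
        model = build_seg_model("pointnet", seed=0)
        res = infer_full_cloud(model, _empty_cloud("cnn"))
        assert res.na and len(res.labels) == 0

    def test_score_scaling_leaves_argmax_unchanged(self, rng):
        scores = rng.random((20, 4))
        s1 = PointScores(scores, np.argmax(scores, 1), np.ones(20, int))
        s2 = PointScores(scores * 50, np.argmax(scores * 50, 1),
                         np.full(20, 50))
        np.testing.assert_array_equal(s1.labels, s2.labels)


class TestSplitByLabel:
    def test_hand_labeled_partition(self, rng):
        cloud, _ = _toy_cloud(rng, 6)
        labels = np.array([0, 1, 1, 2, 3, 0])
        scores = np.eye(4)[labels]
        res = PointScores(scores, labels, np.ones(6, int))
        sets, na = split_by_label(cloud, res)
        assert [len(s) for s in sets] == [2, 1, 1]
        assert na == [False, False, False]
        np.testing.assert_allclose(sets[0], cloud.coords[[1, 2]])
        assert sum(len(s) for s in sets) == (labels > 0).sum()

    def test_all_background_flags_na(self, rng):
        cloud, _ = _toy_cloud(rng, 5)
        labels = np.zeros(5, dtype=np.int64)
        res = PointScores(np.eye(4)[labels], labels, np.ones(5, int))
        sets, na = split_by_label(cloud, res)
        assert na == [True, True, True]
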