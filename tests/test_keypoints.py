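import numpy as np
import pytest
from scipy import ndimage

from fisseg import nn
from fisseg.imaging import Volume
from fisseg.keypoints import (build_preseg_cnn, cnn_keypoints,
                              foerstner_distinctiveness,
                              foerstner_keypoints, fnr_weights,
                              fnr_weighted_ce, nms_select,
                              sliding_window_predict, structure_tensor)


class TestStructureTensor:
    def test_constant_volume_gives_zero_tensor(self):
        S = structure_tensor(Volume(np.full((20, 20, 20), 0.5)))
        assert np.abs(S).max() < 1e-10

    def test_pure_ramp_gives_rank_one_tensor(self):
        g = 0.05
        x = np.arange(32, dtype=np.float64)
        vol = Volume(np.tile((g * x)[:, None, None], (1, 32, 32)))
        S = structure_tensor(vol)
        core = S[10:-10, 10:-10, 10:-10]
        np.testing.assert_allclose(core[..., 0], g ** 2, rtol=1e-3)
        for ch in range(1, 6):
            assert np.abs(core[..., ch]).max() < 1e-8

    def test_finite_difference_gradient_oracle(self, rng):
        """Smoothed-gradient products match an explicit filter pipeline."""
        v = rng.random((24, 24, 24))
        S = structure_tensor(Volume(v), 1.0, 1.5)
        gx = ndimage.gaussian_filter(v, 1.0, order=(1, 0, 0))
        gy = ndimage.gaussian_filter(v, 1.0, order=(0, 1, 0))
        oracle = ndimage.gaussian_filter(gx * gy, 1.5)
        np.testing.assert_allclose(S[..., 3], oracle, atol=1e-12)

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError):
            structure_tensor(Volume(np.zeros((4, 4, 4))))


class TestDistinctiveness:
    def test_identity_tensor(self):
        S = np.zeros((2, 2, 2, 6))
        S[..., :3] = 1.0
        np.testing.assert_allclose(
            foerstner_distinctiveness(S, eps=0.0), 1.0 / 3.0)

    def test_isotropic_scaling(self):
        S = np.zeros((3, 3, 3, 6))
        S[..., :3] = 0.7
        np.testing.assert_allclose(
            foerstner_distinctiveness(S, eps=0.0), 0.7 / 3.0, rtol=1e-12)

    def test_rank_deficient_tensor_vanishes_with_small_eps(self):
        S = np.zeros((1, 1, 1, 6))
        S[..., 0] = S[..., 1] = 1.0  # diag(1, 1, 0)
        d = foerstner_distinctiveness(S, eps=1e-6)
        assert 0 <= d[0, 0, 0] < 1e-5

    def test_matches_linalg_inverse_on_random_psd(self, rng):
        a = rng.normal(size=(50, 3, 3))
        psd = np.einsum("nij,nkj->nik", a, a)
        S = np.stack([psd[:, 0, 0], psd[:, 1, 1], psd[:, 2, 2],
                      psd[:, 0, 1], psd[:, 0, 2], psd[:, 1, 2]],
                     axis=-1).reshape(50, 1, 1, 6)
        eps = 1e-6
        d = foerstner_distinctiveness(S, eps=eps).ravel()
        oracle = 1.0 / np.trace(
            np.linalg.inv(psd + eps * np.eye(3)), axis1=1, axis2=2)
        np.testing.assert_allclose(d, oracle, rtol=1e-8)


def brute_force_nms(D, mask, window):
    r = window // 2
    out = []
    for v in np.argwhere(mask):
        sl = tuple(slice(max(0, c - r), c + r + 1) for c in v)
        if D[tuple(v)] >= D[sl].max():
            out.append(v)
    return np.asarray(out).reshape(-1, 3)


class TestNMS:
    def test_single_bump_gives_single_peak(self):
        D = np.zeros((12, 12, 12))
        D[6, 6, 6] = 1.0
        D = ndimage.gaussian_filter(D, 1.5)
        idx = nms_select(D, np.ones_like(D, dtype=bool))
        np.testing.assert_array_equal(idx, [[6, 6, 6]])

    def test_constant_field_plateau_admits_all(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        idx = nms_select(np.ones((6, 6, 6)), mask)
        assert len(idx) == mask.sum()

    def test_two_separated_bumps(self):
        D = np.zeros((20, 8, 8))
        D[3, 4, 4] = D[16, 4, 4] = 1.0
        D = ndimage.gaussian_filter(D, 1.0)
        idx = nms_select(D, np.ones_like(D, dtype=bool))
        assert {tuple(i) for i in idx} == {(3, 4, 4), (16, 4, 4)}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(3):
            D = rng.random((6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.3
            if not mask.any():
                continue
            idx = nms_select(D, mask)
            oracle = brute_force_nms(D, mask, 5)
            np.testing.assert_array_equal(idx, oracle)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            nms_select(np.ones((6, 6, 6)), np.zeros((6, 6, 6), dtype=bool))


class TestFoerstnerKeypoints:
    def test_nonempty_and_inside_mask(self, case64):
        cloud = foerstner_keypoints(case64.volume, case64.lung_mask,
                                    k_max=20000)
        assert len(cloud) >= 1
        vi = cloud.voxel_indices
        assert case64.lung_mask[vi[:, 0], vi[:, 1], vi[:, 2]].all()
        assert np.all(np.abs(cloud.coords) <= 1.0)
        assert cloud.features.shape == (len(cloud), 125)

    def test_k_max_keeps_largest_distinctiveness(self, case64):
        full = foerstner_keypoints(case64.volume, case64.lung_mask,
                                   k_max=10 ** 6)
        assert len(full) > 5
        top5 = foerstner_keypoints(case64.volume, case64.lung_mask, k_max=5)
        assert len(top5) == 5
        # recompute D to check the 5 selected are the global top-5
        from fisseg.imaging import normalize_intensity
        from fisseg.keypoints import (foerstner_distinctiveness,
                                      structure_tensor)
        D = foerstner_distinctiveness(
            structure_tensor(normalize_intensity(case64.volume)))
        all_scores = np.sort(
            D[full.voxel_indices[:, 0], full.voxel_indices[:, 1],
              full.voxel_indices[:, 2]])[::-1]
        sel_scores = np.sort(
            D[top5.voxel_indices[:, 0], top5.voxel_indices[:, 1],
              top5.voxel_indices[:, 2]])[::-1]
        np.testing.assert_allclose(sel_scores, all_scores[:5])


class TestFnrLoss:
    def test_all_missed_class_gets_weight_one(self):
        true = np.array([0, 0, 1, 1, 1])
        pred = np.zeros(5, dtype=int)
        w = fnr_weights(pred, true)
        assert w[1] == 1.0 and w[0] == 0.0
        assert w[2] == 0.0 and w[3] == 0.0  # absent classes

    def test_perfect_prediction_zero_weights_zero_loss(self):
        true = np.array([0, 1, 2, 3])
        assert np.all(fnr_weights(true, true) == 0)
        logits = nn.Tensor(np.eye(4, dtype=np.float32) * 20)
        assert float(fnr_weighted_ce(logits, true).data) == pytest.approx(0.0)

    def test_half_missed_counting_oracle(self):
        true = np.array([2] * 6 + [0] * 4)
        pred = np.array([2, 2, 2, 0, 0, 0, 0, 0, 0, 0])
        assert fnr_weights(pred, true)[2] == pytest.approx(0.5)

    def test_weights_in_unit_interval_and_permutation_invariant(self, rng):
        true = rng.integers(0, 4, 50)
        pred = rng.integers(0, 4, 50)
        w = fnr_weights(pred, true)
        assert np.all((w >= 0) & (w <= 1))
        perm = rng.permutation(50)
        np.testing.assert_array_equal(w, fnr_weights(pred[perm], true[perm]))

    def test_weights_recomputed_per_batch(self, rng):
        logits = nn.Tensor(rng.normal(size=(8, 4)).astype(np.float32))
        l1 = float(fnr_weighted_ce(logits, np.array([1] * 8)).data)
        l2 = float(fnr_weighted_ce(logits, np.array([2] * 8)).data)
        assert l1 != l2

    def test_missed_foreground_gradient_dominates(self):
        """With FNR_fg > FNR_bg a missed foreground voxel drives the loss
        harder than an equally confident missed background voxel."""
        logits = np.zeros((4, 4), dtype=np.float32)
        logits[0, 1] = 2.0   # bg voxel predicted class 1 (missed bg)
        logits[1, 0] = 2.0   # fg voxel predicted bg (missed fg)
        true = np.array([0, 1, 0, 0])  # bg FNR = 1/3, fg FNR = 1
        t = nn.Tensor(logits, requires_grad=True)
        loss = fnr_weighted_ce(t, true)
        loss.backward()
        g = t.grad
        # gradient pushing up the correct logit of the missed fg voxel
        assert abs(g[1, 1]) > abs(g[0, 0])


class TestPresegCNN:
    def test_output_contract(self):
        model = build_preseg_cnn(seed=0)
        x = np.random.default_rng(0).random((1, 32, 32, 32)).astype(np.float32)
        out = model(x)
        assert out.shape == (4, 32, 32, 32)
        assert np.isfinite(out).all()

    def test_sliding_window_coverage_and_simplex(self):
        model = build_preseg_cnn(seed=0)
        vol = Volume(np.random.default_rng(1).random((48, 40, 32))
                     .astype(np.float32))
        probs = sliding_window_predict(model, vol, patch=32, overlap=0.5)
        assert probs.shape == (4,) + vol.shape
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert np.all(probs >= 0)

    def test_single_patch_equals_direct_softmax(self):
        model = build_preseg_cnn(seed=0)
        v = np.random.default_rng(2).random((32, 32, 32)).astype(np.float32)
        probs = sliding_window_predict(model, Volume(v), patch=32)
        logits = model(v[None])
        e = np.exp(logits - logits.max(axis=0, keepdims=True))
        np.testing.assert_allclose(probs, e / e.sum(axis=0, keepdims=True),
                                   atol=1e-6)


class TestCnnKeypoints:
    def _probmap(self, fg_idx, shape=(16, 16, 16)):
        probs = np.zeros((4,) + shape)
        probs[0] = 0.9
        for i in fg_idx:
            probs[:, i[0], i[1], i[2]] = [0.1, 0.8, 0.05, 0.05]
        return probs

    def test_few_predictions_all_kept(self, rng):
        fg = [(2, 3, 4), (5, 5, 5), (10, 11, 12)]
        vol = Volume(rng.random((16, 16, 16)))
        cloud = cnn_keypoints(self._probmap(fg), np.ones((16, 16, 16), bool),
                              vol, k_max=20000, seed=0)
        assert len(cloud) == 3
        assert {tuple(v) for v in cloud.voxel_indices} == set(fg)

    def test_oversized_prediction_sampled_to_k_max(self, rng):
        fg = [tuple(v) for v in np.argwhere(np.ones((8, 8, 8)))]
        probs = self._probmap(fg, (8, 8, 8))
        vol = Volume(rng.random((8, 8, 8)))
        cloud = cnn_keypoints(probs, np.ones((8, 8, 8), bool), vol,
                              k_max=100, seed=3)
        assert len(cloud) == 100
        assert {tuple(v) for v in cloud.voxel_indices} <= set(fg)

    def test_zero_predictions_flagged_na(self, rng):
        vol = Volume(rng.random((16, 16, 16)))
        cloud = cnn_keypoints(self._probmap([]), np.ones((16, 16, 16), bool),
                              vol, seed=0)
        assert cloud.is_empty
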