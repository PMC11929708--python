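"""Sparse keypoint extraction from CT-like volumes.

Two sources are supported:

* **Förstner keypoints** — fissure-agnostic.  The image structure tensor
  S = G_sigma_t * (∇I ∇Iᵀ) is computed from Gaussian-derivative gradients,
  the Förstner distinctiveness D = 1 / trace((S + eps I)^-1) scores every
  voxel, and local maxima of D in 5x5x5 neighborhoods inside the lung mask
  become keypoints (top-K by distinctiveness if over budget).

* **CNN keypoints** — fissure-specific.  A lightweight 3D MobileNetV3
  pre-segmentation proposes fissure voxels; K points are sampled at random
  from the proposals.  An empty proposal set is a valid, flagged outcome
  that propagates as "non-assigned" downstream.

Both attach 125-dim intensity-patch features and normalized coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .imaging import (Volume, extract_patch_features, normalize_intensity,
                      voxel_to_norm)
from .mobilenet3d import MobileNetV3Seg3D

DEFAULT_K_MAX = 20_000


@dataclass
class KeypointCloud:
    coords: np.ndarray         # (K, 3) in [-1, 1]
    voxel_indices: np.ndarray  # (K, 3) int
    features: np.ndarray       # (K, 125)
    source: str                # "foerstner" | "cnn"

    def __len__(self):
        return len(self.coords)

    @property
    def is_empty(self) -> bool:
        return len(self.coords) == 0

    def save(self, path):
        np.savez(path, coords=self.coords, voxel_indices=self.voxel_indices,
                 features=self.features, source=self.source)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as data:
            return cls(data["coords"], data["voxel_indices"],
                       data["features"], str(data["source"]))


def _empty_cloud(source: str) -> KeypointCloud:
    return KeypointCloud(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64),
                         np.zeros((0, 125), dtype=np.float32), source)


# ---------------------------------------------------------------------------
# Förstner operator
# ---------------------------------------------------------------------------

def structure_tensor(vol: Volume, sigma_grad: float = 1.0,
                     sigma_tensor: float = 1.5) -> np.ndarray:
    """Smoothed outer product of Gaussian-derivative gradients.

    Returns the 6 independent channels (xx, yy, zz, xy, xz, yz) stacked on
    the last axis, shape ``vol.shape + (6,)``.
    """
    if sigma_grad <= 0 or sigma_tensor <= 0:
        raise ValueError("smoothing scales must be positive")
    support = 2 * int(4 * max(sigma_grad, sigma_tensor) + 0.5) + 1
    if min(vol.shape) < support:
        raise ValueError(
            f"volume smaller than the filter support ({support} voxels)")
    img = vol.voxels.astype(np.float64)
    grads = [ndimage.gaussian_filter(img, sigma_grad, order=tuple(
        int(a == ax) for a in range(3))) for ax in range(3)]
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    chans = [ndimage.gaussian_filter(grads[i] * grads[j], sigma_tensor)
             for i, j in pairs]
    return np.stack(chans, axis=-1)


def foerstner_distinctiveness(S: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """D = 1/trace((S + eps I)^-1) = det(A)/trace(adj(A)), closed form 3x3."""
    xx = S[..., 0] + eps
    yy = S[..., 1] + eps
    zz = S[..., 2] + eps
    xy, xz, yz = S[..., 3], S[..., 4], S[..., 5]
    det = (xx * (yy * zz - yz ** 2) - xy * (xy * zz - yz * xz)
           + xz * (xy * yz - yy * xz))
    tr_adj = ((yy * zz - yz ** 2) + (xx * zz - xz ** 2)
              + (xx * yy - xy ** 2))
    D = det / np.maximum(tr_adj, 1e-300)
    return np.maximum(D, 0.0)


def nms_select(D: np.ndarray, mask: np.ndarray, window: int = 5) -> np.ndarray:
    """Voxels that attain the neighborhood maximum of D inside the mask.

    Plateau rule: ties with the local maximum are admitted, so a constant
    field yields every masked voxel — the candidate set is never empty for
    a non-empty mask.  Output indices are sorted lexicographically.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    local_max = ndimage.maximum_filter(D, size=window, mode="nearest")
    selected = mask & (D >= local_max)
    return np.argwhere(selected)


def foerstner_keypoints(vol: Volume, mask: np.ndarray,
                        k_max: int = DEFAULT_K_MAX,
                        sigma_grad: float = 1.0, sigma_tensor: float = 1.5,
                        eps: float = 1e-6, window: int = 5,
                        intensity_window=None) -> KeypointCloud:
    """Full Förstner chain: tensor -> distinctiveness -> NMS -> top-K."""
    from .imaging import DEFAULT_WINDOW

    norm = normalize_intensity(vol, intensity_window or DEFAULT_WINDOW)
    S = structure_tensor(norm, sigma_grad, sigma_tensor)
    D = foerstner_distinctiveness(S, eps)
    idx = nms_select(D, mask, window)
    if len(idx) > k_max:
        scores = D[idx[:, 0], idx[:, 1], idx[:, 2]]
        # stable sort on -D keeps lexicographic order among exact ties
        order = np.argsort(-scores, kind="stable")[:k_max]
        idx = idx[np.sort(order)]  # keep lexicographic layout of survivors
    coords = voxel_to_norm(idx, vol.shape)
    feats = extract_patch_features(norm, idx)
    return KeypointCloud(coords, idx, feats, "foerstner")


# ---------------------------------------------------------------------------
# Recall-promoting loss for the pre-segmentation CNN
# ---------------------------------------------------------------------------

def fnr_weights(pred_labels: np.ndarray, true_labels: np.ndarray,
                n_classes: int = 4) -> np.ndarray:
    """Per-class false-negative rate FN/(FN+TP) from hard predictions.

    Classes absent from the ground truth get weight 0.  Computed per batch;
    plain numpy, hence detached from any gradient by construction.
    """
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction/ground-truth shape mismatch")
    w = np.zeros(n_classes, dtype=np.float32)
    for c in range(n_classes):
        gt_c = true == c
        n_c = int(gt_c.sum())
        if n_c == 0:
            continue
        tp = int((pred[gt_c] == c).sum())
        w[c] = (n_c - tp) / n_c
    return w


def fnr_weighted_ce(logits: "nn.Tensor", true_labels: np.ndarray) -> "nn.Tensor":
    """Cross-entropy weighted by the batch's per-class false-negative rate.

    High-FNR classes dominate the loss, pushing the segmentation toward
    high recall.  With a perfect prediction all weights are zero and the
    loss is exactly 0.
    """
    true = np.asarray(true_labels).ravel()
    if logits.shape[0] != true.shape[0]:
        raise ValueError("logits/labels shape mismatch")
    pred = np.argmax(logits.data, axis=-1)
    w = fnr_weights(pred, true, n_classes=logits.shape[-1])
    return nn.cross_entropy(logits, true, weights=w)


# ---------------------------------------------------------------------------
# CNN keypoints
# ---------------------------------------------------------------------------

def build_preseg_cnn(in_channels: int = 1, n_classes: int = 4,
                     seed: int | None = None) -> MobileNetV3Seg3D:
    if seed is not None:
        nn.manual_seed(seed)
    return MobileNetV3Seg3D(in_channels, n_classes)


def sliding_window_predict(model: MobileNetV3Seg3D, vol: Volume,
                           patch: int = 128,
                           overlap: float = 0.5) -> np.ndarray:
    """Tile the volume with >= `overlap` overlapping patches and average
    the per-patch softmax maps uniformly.  Returns (n_classes, *shape)
    probabilities summing to 1 per voxel."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    v = vol.voxels.astype(np.float32)
    shape = v.shape
    pads = [(0, max(0, patch - s)) for s in shape]
    v = np.pad(v, pads, mode="edge")
    stride = max(1, int(patch * (1.0 - overlap)))

    def starts(n):
        if n <= patch:
            return [0]
        s = list(range(0, n - patch, stride))
        s.append(n - patch)
        return s

    acc = None
    count = np.zeros(v.shape, dtype=np.float32)
    for x0 in starts(v.shape[0]):
        for y0 in starts(v.shape[1]):
            for z0 in starts(v.shape[2]):
                tile = v[None, x0:x0 + patch, y0:y0 + patch, z0:z0 + patch]
                logits = model(tile)
                e = np.exp(logits - logits.max(axis=0, keepdims=True))
                probs = e / e.sum(axis=0, keepdims=True)
                if acc is None:
                    acc = np.zeros((probs.shape[0],) + v.shape,
                                   dtype=np.float32)
                acc[:, x0:x0 + patch, y0:y0 + patch, z0:z0 + patch] += probs
                count[x0:x0 + patch, y0:y0 + patch, z0:z0 + patch] += 1
    acc /= count[None]
    return acc[:, :shape[0], :shape[1], :shape[2]]


def cnn_keypoints(probmap: np.ndarray, mask: np.ndarray, vol: Volume,
                  k_max: int = DEFAULT_K_MAX, seed: int = 0,
                  intensity_window=None) -> KeypointCloud:
    """Sample K keypoints uniformly from predicted fissure voxels.

    `probmap` is (4, *shape) class probabilities; foreground is any
    non-background argmax inside the lung mask.  Zero proposals yield an
    empty cloud (the non-assigned pathway, not an error).
    """
    from .imaging import DEFAULT_WINDOW

    if probmap.shape[0] != 4:
        raise ValueError("expected 4-class probability map")
    fg = (np.argmax(probmap, axis=0) != 0) & np.asarray(mask, dtype=bool)
    idx = np.argwhere(fg)
    if len(idx) == 0:
        return _empty_cloud("cnn")
    if len(idx) > k_max:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(idx), size=k_max, replace=False)
        idx = idx[np.sort(keep)]
    norm = normalize_intensity(vol, intensity_window or DEFAULT_WINDOW)
    coords = voxel_to_norm(idx, vol.shape)
    feats = extract_patch_features(norm, idx)
    return KeypointCloud(coords, idx, feats, "cnn")
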