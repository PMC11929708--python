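"""Point-cloud segmentation networks and their training/inference loops.

Three architecture families label each keypoint with one of four classes
(background + three fissures):

* **PointNet** — shared per-point MLPs, a global max-pool and a
  concatenated segmentation head; no spatial transformer.
* **DGCNN** — a stack of EdgeConv graph convolutions over a kNN graph
  (k = 40) built once from the point coordinates and reused by every
  layer (the "dynamic" graph rebuild is deliberately disabled).
* **PointTransformer** — a U-Net style encoder-decoder with vector
  self-attention in k = 16 neighborhoods and learned position encodings
  added to both the attention weights and the aggregated features.

Channel widths are chosen so the trainable-parameter counts land on the
published budgets (0.48 M / 0.65 M / 7.77 M).

Training samples N = 2048 points per forward pass, optimizes a combined
cross-entropy + soft-Dice loss with Adam (lr 1e-3, weight decay 1e-5) and
a cosine schedule decaying to 5 % of the initial rate, under random rigid
augmentation.  Full-cloud inference accumulates softmax scores over 50
passes with coverage-first subset sampling so every point is labeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .keypoints import KeypointCloud

N_CLASSES = 4
FEATURE_DIM = 125
C_IN = 3 + FEATURE_DIM


# ---------------------------------------------------------------------------
# kNN graph
# ---------------------------------------------------------------------------

@dataclass
class KnnGraph:
    k: int
    neighbors: np.ndarray  # (n, k) indices, self excluded


def knn_graph(coords: np.ndarray, k: int) -> KnnGraph:
    """Euclidean kNN on coordinates only; ties broken by lower index."""
    pts = np.asarray(coords, dtype=np.float64)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points for a kNN graph")
    k_eff = min(k, n - 1)
    if n <= 512:
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        # stable argsort: equal distances resolve to the lower index
        nbr = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    else:
        _, nbr = cKDTree(pts).query(pts, k=k_eff + 1)
        self_col = nbr == np.arange(n)[:, None]
        # remove self wherever it appears; if absent (duplicates), drop last
        keep = ~self_col
        extra = keep.sum(axis=1) - k_eff
        rows = np.where(extra > 0)[0]
        for r in rows:
            last = np.where(keep[r])[0][-1]
            keep[r, last] = False
        nbr = nbr[keep].reshape(n, k_eff)
    return KnnGraph(k=k_eff, neighbors=nbr.astype(np.int64))


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class EdgeConv(nn.Module):
    """max_j MLP([x_i, x_j - x_i]) over the fixed neighbor lists."""

    def __init__(self, c_in: int, c_out: int):
        super().__init__()
        self.lin = nn.Linear(2 * c_in, c_out, bias=False)
        self.bn = nn.BatchNorm(c_out)

    def forward(self, x: nn.Tensor, nbr: np.ndarray) -> nn.Tensor:
        n, k = nbr.shape
        xj = x[nbr]                                        # (n, k, C)
        xi = x.reshape(n, 1, x.shape[-1]).broadcast_to(xj.shape)
        edge = nn.concat([xi, xj - xi], axis=-1)
        h = self.bn(self.lin(edge)).leaky_relu(0.2)
        return h.max(axis=1)


class PointNetSeg(nn.Module):
    """PointNet segmentation network without T-Net."""

    arch = "pointnet"
    needs_graph = False

    def __init__(self, c_in: int = C_IN, n_classes: int = N_CLASSES,
                 widths=(64, 64, 128, 576), head=(384, 256, 128)):
        super().__init__()
        w = widths
        self.local = nn.mlp([c_in, w[0], w[0]])
        self.enc = nn.mlp([w[0], w[1], w[2], w[3]])
        self.head = nn.mlp([w[0] + w[3], head[0], head[1], head[2]])
        self.out = nn.Linear(head[2], n_classes)

    def forward(self, coords, features, graph=None):
        x = nn.concat([_t(coords), _t(features)], axis=-1)
        local = self.local(x)                       # (n, w0)
        enc = self.enc(local)                       # (n, w3)
        glob = enc.max(axis=0)                      # (w3,)
        n = local.shape[0]
        glob_rep = glob.reshape(1, -1).broadcast_to((n, glob.shape[0]))
        h = self.head(nn.concat([local, glob_rep], axis=-1))
        return self.out(h)


class DGCNNSeg(nn.Module):
    """EdgeConv stack on one static kNN graph (k = 40), PointNet-style head."""

    arch = "dgcnn"
    needs_graph = True

    def __init__(self, c_in: int = C_IN, n_classes: int = N_CLASSES, k: int = 40,
                 ec_widths=(64, 64, 96), global_width=736, head=(384, 192)):
        super().__init__()
        self.k = k
        self.ec1 = EdgeConv(c_in, ec_widths[0])
        self.ec2 = EdgeConv(ec_widths[0], ec_widths[1])
        self.ec3 = EdgeConv(ec_widths[1], ec_widths[2])
        cat = sum(ec_widths)
        self.pre_pool = nn.mlp([cat, global_width])
        self.head = nn.mlp([cat + global_width, head[0], head[1]])
        self.out = nn.Linear(head[1], n_classes)

    def forward(self, coords, features, graph: KnnGraph | None = None):
        if graph is None:
            graph = knn_graph(coords, self.k)
        nbr = graph.neighbors
        x = nn.concat([_t(coords), _t(features)], axis=-1)
        h1 = self.ec1(x, nbr)
        h2 = self.ec2(h1, nbr)
        h3 = self.ec3(h2, nbr)
        cat = nn.concat([h1, h2, h3], axis=-1)
        glob = self.pre_pool(cat).max(axis=0)
        n = cat.shape[0]
        glob_rep = glob.reshape(1, -1).broadcast_to((n, glob.shape[0]))
        h = self.head(nn.concat([cat, glob_rep], axis=-1))
        return self.out(h)


class VectorAttention(nn.Module):
    """Vector self-attention in kNN neighborhoods with position encoding.

    w_ij = softmax_j(gamma(q_i - k_j + delta_ij)), applied per channel
    group (share factor s); y_i = sum_j w_ij * (v_j + delta_ij).
    """

    def __init__(self, channels: int, share: int = 8):
        super().__init__()
        self.share = share
        self.q = nn.Linear(channels, channels, bias=False)
        self.k = nn.Linear(channels, channels, bias=False)
        self.v = nn.Linear(channels, channels, bias=False)
        self.pos = nn.Sequential(nn.Linear(3, 3), nn.ReLU(),
                                 nn.Linear(3, channels))
        mid = channels // share
        self.gamma = nn.Sequential(nn.Linear(channels, mid), nn.ReLU(),
                                   nn.Linear(mid, mid))

    def forward(self, x: nn.Tensor, pts: np.ndarray, nbr: np.ndarray):
        n, k = nbr.shape
        c = x.shape[-1]
        q, kk, v = self.q(x), self.k(x), self.v(x)
        rel = pts[:, None, :] - pts[nbr]                    # (n, k, 3)
        delta = self.pos(_t(rel))
        kj = kk[nbr]
        vj = v[nbr] + delta
        qi = q.reshape(n, 1, c).broadcast_to((n, k, c))
        a = self.gamma(qi - kj + delta)                     # (n, k, c/s)
        w = nn.softmax(a, axis=1)
        s = self.share
        w_full = w.reshape(n, k, c // s, 1).broadcast_to(
            (n, k, c // s, s)).reshape(n, k, c)
        return (w_full * vj).sum(axis=1)


class PTBlock(nn.Module):
    def __init__(self, channels: int, share: int = 8):
        super().__init__()
        self.lin1 = nn.Linear(channels, channels)
        self.attn = VectorAttention(channels, share)
        self.lin2 = nn.Linear(channels, channels)
        self.bn = nn.BatchNorm(channels)

    def forward(self, x, pts, nbr):
        h = self.lin1(x).relu()
        h = self.attn(h, pts, nbr)
        h = self.lin2(h)
        return self.bn(x + h).relu()


class TransitionDown(nn.Module):
    """FPS to n/stride points, local max-pool of MLP'd neighbor features."""

    def __init__(self, c_in: int, c_out: int, stride: int = 4, k: int = 16):
        super().__init__()
        self.stride, self.k = stride, k
        self.lin = nn.Linear(c_in + 3, c_out, bias=False)
        self.bn = nn.BatchNorm(c_out)

    def forward(self, x, pts):
        from .pc_ae import fps

        n = len(pts)
        m = max(1, n // self.stride)
        # geometry-determined start keeps the whole model permutation-
        # equivariant (an index-based start would not be)
        start = int(np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))[0])
        sel = fps(pts, m, start=start)
        sub = pts[sel]
        k = min(self.k, n)
        _, nbr = cKDTree(pts).query(sub, k=k)
        nbr = nbr.reshape(m, k)
        rel = pts[nbr] - sub[:, None, :]
        feats = nn.concat([x[nbr], _t(rel)], axis=-1)
        h = self.bn(self.lin(feats)).relu()
        return h.max(axis=1), sub, sel


class TransitionUp(nn.Module):
    """3-NN inverse-distance interpolation of coarse features + skip."""

    def __init__(self, c_coarse: int, c_fine: int):
        super().__init__()
        self.lin_coarse = nn.Sequential(nn.Linear(c_coarse, c_fine),
                                        nn.ReLU())
        self.lin_fine = nn.Sequential(nn.Linear(c_fine, c_fine), nn.ReLU())

    def forward(self, x_coarse, pts_coarse, x_fine, pts_fine):
        k = min(3, len(pts_coarse))
        d, idx = cKDTree(pts_coarse).query(pts_fine, k=k)
        d = d.reshape(len(pts_fine), k)
        idx = idx.reshape(len(pts_fine), k)
        w = 1.0 / np.maximum(d, 1e-10)
        w = (w / w.sum(axis=1, keepdims=True)).astype(np.float32)
        interp = (self.lin_coarse(x_coarse)[idx] * _t(w[..., None])).sum(axis=1)
        return self.lin_fine(x_fine) + interp


class PointTransformerSeg(nn.Module):
    """Encoder-decoder with vector attention in k = 16 neighborhoods."""

    arch = "pointtransformer"
    needs_graph = False

    def __init__(self, c_in: int = C_IN, n_classes: int = N_CLASSES,
                 planes=(32, 64, 128, 256, 704), blocks=(1, 2, 3, 4, 2),
                 k: int = 16, stride: int = 4, share: int = 8):
        super().__init__()
        self.k = k
        p = list(planes)
        self.embed = nn.mlp([c_in, p[0], p[0]], act="relu")
        self.enc_blocks = [
            [PTBlock(p[i], share) for _ in range(blocks[i])]
            for i in range(len(p))
        ]
        self.downs = [TransitionDown(p[i], p[i + 1], stride, k)
                      for i in range(len(p) - 1)]
        self.ups = [TransitionUp(p[i + 1], p[i]) for i in range(len(p) - 1)]
        self.dec_blocks = [[PTBlock(p[i], share)] for i in range(len(p) - 1)]
        self.head = nn.mlp([p[0], p[0]], act="relu")
        self.out = nn.Linear(p[0], n_classes)

    def _nbr(self, pts):
        k = min(self.k, len(pts) - 1) if len(pts) > 1 else 1
        if len(pts) == 1:
            return np.zeros((1, 1), dtype=np.int64)
        return knn_graph(pts, k).neighbors

    def forward(self, coords, features, graph=None):
        pts = np.asarray(coords, dtype=np.float64)
        x = self.embed(nn.concat([_t(coords), _t(features)], axis=-1))
        skips = []
        for i, blocks in enumerate(self.enc_blocks):
            nbr = self._nbr(pts)
            for b in blocks:
                x = b(x, pts, nbr)
            if i < len(self.downs):
                skips.append((x, pts))
                x, pts, _ = self.downs[i](x, pts)
        for i in reversed(range(len(self.ups))):
            x_fine, pts_fine = skips[i]
            x = self.ups[i](x, pts, x_fine, pts_fine)
            pts = pts_fine
            nbr = self._nbr(pts)
            for b in self.dec_blocks[i]:
                x = b(x, pts, nbr)
        return self.out(self.head(x))


def _t(a) -> nn.Tensor:
    return a if isinstance(a, nn.Tensor) else nn.Tensor(
        np.asarray(a, dtype=np.float32))


# ---------------------------------------------------------------------------
# Factory / forward / loss
# ---------------------------------------------------------------------------

ARCHS = {
    "pointnet": PointNetSeg,
    "dgcnn": DGCNNSeg,
    "pointtransformer": PointTransformerSeg,
}


def build_seg_model(arch: str, c_in: int = C_IN,
                    n_classes: int = N_CLASSES, seed: int | None = None,
                    **kwargs):
    if arch not in ARCHS:
        raise ValueError(f"unknown architecture {arch!r}")
    if seed is not None:
        nn.manual_seed(seed)
    return ARCHS[arch](c_in=c_in, n_classes=n_classes, **kwargs)


def seg_forward(model, coords, features, graph: KnnGraph | None = None):
    """(n,3) coords + (n,125) features -> (n,4) logits Tensor."""
    if len(coords) != len(features):
        raise ValueError("coords/features row mismatch")
    return model(coords, features, graph)


DICE_SMOOTH = 1e-5


def ce_dice_loss(logits: nn.Tensor, labels: np.ndarray,
                 n_classes: int = N_CLASSES) -> nn.Tensor:
    """Cross-entropy plus mean (1 - soft Dice) over all classes."""
    labels = np.asarray(labels)
    if logits.shape[0] != labels.shape[0]:
        raise ValueError("logits/labels shape mismatch")
    ce = nn.cross_entropy(logits, labels)
    probs = nn.softmax(logits, axis=-1)
    onehot = np.eye(n_classes, dtype=np.float32)[labels]
    inter = (probs * onehot).sum(axis=0)
    denom = probs.sum(axis=0) + onehot.sum(axis=0)
    dice = (inter * 2.0 + DICE_SMOOTH) / (denom + DICE_SMOOTH)
    return ce + (1.0 - dice).mean()


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentRanges:
    rot_deg: float = 15.0
    translation: float = 0.1
    scale: tuple = (0.9, 1.1)


def rigid_augment(coords: np.ndarray, rng, ranges: AugmentRanges | None = None
                  ) -> np.ndarray:
    """One random similarity transform (R, s, t) applied to the whole cloud."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ranges = ranges or AugmentRanges()
    ang = np.deg2rad(rng.uniform(-ranges.rot_deg, ranges.rot_deg, 3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    s = rng.uniform(*ranges.scale)
    t = rng.uniform(-ranges.translation, ranges.translation, 3)
    return (np.asarray(coords) @ rot.T) * s + t


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    epochs: int = 1000
    lr: float = 1e-3
    weight_decay: float = 1e-5
    floor_factor: float = 0.05
    n_points: int = 2048
    k_graph: int = 40
    augment: AugmentRanges = field(default_factory=AugmentRanges)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.floor_factor <= 1:
            raise ValueError("floor factor must be in (0, 1]")


def train_seg(model, cases, config: SegTrainConfig):
    """Train on (cloud, labels) pairs; returns the per-step loss history.

    Each step draws n_points uniformly without replacement from one case
    (with replacement only if the case is smaller), augments the
    coordinates rigidly and takes one Adam step on the CE+Dice loss.
    """
    if not cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)
    sched = nn.CosineAnnealing(opt, config.epochs, config.floor_factor)
    history = []
    model.train()
    for epoch in range(config.epochs):
        sched.step(epoch)
        order = rng.permutation(len(cases))
        for ci in order:
            cloud, labels = cases[ci][0], cases[ci][1]
            coords, feats = cloud.coords, cloud.features
            n = len(coords)
            if n >= config.n_points:
                sel = rng.choice(n, size=config.n_points, replace=False)
            else:
                sel = rng.choice(n, size=config.n_points, replace=True)
            c = rigid_augment(coords[sel], rng, config.augment)
            graph = (knn_graph(c, config.k_graph)
                     if getattr(model, "needs_graph", False) else None)
            logits = seg_forward(model, c, feats[sel], graph)
            loss = ce_dice_loss(logits, np.asarray(labels)[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass
class PointScores:
    scores: np.ndarray    # (n, 4) accumulated softmax scores
    labels: np.ndarray    # (n,) argmax, lowest class index wins ties
    coverage: np.ndarray  # (n,) number of forward passes per point
    na: bool = False


def infer_full_cloud(model, cloud: KeypointCloud, rounds: int = 50,
                     n_points: int = 2048, seed: int = 0,
                     k_graph: int = 40) -> PointScores:
    """Accumulate softmax scores over `rounds` random subsets.

    Subsets are drawn coverage-first: not-yet-covered points are exhausted
    before covered ones are resampled, so every point is segmented; extra
    rounds are appended in the rare case `rounds` passes cannot cover the
    cloud.
    """
    if cloud.is_empty:
        return PointScores(np.zeros((0, N_CLASSES)), np.zeros(0, np.int64),
                           np.zeros(0, np.int64), na=True)
    rng = np.random.default_rng(seed)
    n = len(cloud)
    n_pass = min(n_points, n)
    scores = np.zeros((n, N_CLASSES), dtype=np.float64)
    coverage = np.zeros(n, dtype=np.int64)
    model.eval()
    done = 0
    while done < rounds or coverage.min() == 0:
        uncovered = np.where(coverage == 0)[0]
        if len(uncovered) >= n_pass:
            sel = rng.choice(uncovered, size=n_pass, replace=False)
        elif len(uncovered) > 0:
            rest = np.where(coverage > 0)[0]
            fill = rng.choice(rest, size=n_pass - len(uncovered),
                              replace=False)
            sel = np.concatenate([uncovered, fill])
        else:
            sel = rng.choice(n, size=n_pass, replace=False)
        coords = cloud.coords[sel]
        graph = (knn_graph(coords, k_graph)
                 if getattr(model, "needs_graph", False) else None)
        with nn.no_grad():
            logits = seg_forward(model, coords, cloud.features[sel], graph)
            probs = nn.softmax(logits, axis=-1).data
        scores[sel] += probs
        coverage[sel] += 1
        done += 1
    labels = np.argmax(scores, axis=1)  # np.argmax: first (lowest) index wins
    return PointScores(scores, labels, coverage)


def split_by_label(cloud: KeypointCloud, result: PointScores):
    """Coordinate subsets for fissure classes 1..3 plus n.a. flags."""
    sets, na = [], []
    for cls in (1, 2, 3):
        pts = cloud.coords[result.labels == cls] if len(cloud) else \
            np.zeros((0, 3))
        sets.append(pts)
        na.append(len(pts) == 0)
    return sets, na


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, extra: dict | None = None):
    meta = {"arch": model.arch}
    meta.update(extra or {})
    state = model.state_dict()
    np.savez(path, __meta__=json.dumps(meta),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path, **build_kwargs):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model = build_seg_model(meta["arch"], **build_kwargs)
    model.load_state_dict(state)
    return model, meta
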