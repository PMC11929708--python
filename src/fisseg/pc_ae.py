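"""Point-cloud-to-mesh autoencoder (PC-AE).

A DGCNN-style EdgeConv encoder compresses an N-point cloud into a latent
code z (h = 512, global max-pool, permutation-invariant).  The decoder
deforms a fissure-homeomorphic template — a flat square grid of M vertices
(M the closest square number to N) bilinearly sampled over
[-0.3, 0.3]^2 at z = 0 — in two residual steps:

    V1 = V0 + f1([z, V0]),   V2 = V1 + f2([z, V1])

with f1, f2 shared per-vertex MLPs R^(h+3) -> R^3.  Connectivity and
vertex order are template-fixed, giving cross-shape correspondence.

Training minimizes a regularized mesh loss: squared chamfer distance of
the decoded vertices to the target points plus normal-consistency (NC),
edge-length (EL) and Laplacian-smoothness (LS) terms, weighted
1 / 0.1 / 1 / 0.1.  Inference feeds exactly N points: larger clouds are
reduced by farthest point sampling, sparser ones padded with
randomly-offset duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import nn
from .pointseg import EdgeConv, knn_graph


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

@dataclass
class TemplatePlane:
    vertices: np.ndarray     # (M, 3), z = 0
    faces: np.ndarray        # (2 (sqrt(M)-1)^2, 3)
    grid_size: int

    @property
    def n_vertices(self):
        return len(self.vertices)


def closest_square(n: int) -> int:
    s = int(np.floor(np.sqrt(n)))
    candidates = [s ** 2, (s + 1) ** 2]
    return min(candidates, key=lambda c: (abs(c - n), c))


def make_template(n_points: int, half_extent: float = 0.3) -> TemplatePlane:
    """Regular sqrt(M) x sqrt(M) grid over [-0.3, 0.3]^2, fixed diagonal."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    m = closest_square(n_points)
    s = int(np.sqrt(m))
    axis = np.linspace(-half_extent, half_extent, s)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(m)])
    faces = []
    for i in range(s - 1):
        for j in range(s - 1):
            v00 = i * s + j
            v10 = (i + 1) * s + j
            v01 = i * s + j + 1
            v11 = (i + 1) * s + j + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return TemplatePlane(verts, np.asarray(faces, dtype=np.int64), s)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def fps(points: np.ndarray, n_select: int, start: int = 0) -> np.ndarray:
    """Greedy farthest point sampling; deterministic start (index 0).

    Each added point maximizes the minimum distance to the selected set;
    exact ties resolve to the lowest index (numpy argmax convention).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n == 0:
        raise ValueError("empty point set")
    m = min(n_select, n)
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = start
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen


def pad_cloud(points: np.ndarray, n_target: int, sigma_pad: float = 0.05,
              seed: int = 0) -> np.ndarray:
    """Pad to n_target by duplicating random points with Gaussian offsets."""
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n == 0:
        raise ValueError("cannot pad an empty cloud")
    if n > n_target:
        raise ValueError("cloud larger than target; use fps instead")
    if n == n_target:
        return pts.copy()
    rng = np.random.default_rng(seed)
    src = rng.integers(0, n, size=n_target - n)
    extra = pts[src] + rng.normal(0.0, sigma_pad, (n_target - n, 3))
    return np.concatenate([pts, extra], axis=0)


# ---------------------------------------------------------------------------
# Chamfer distance
# ---------------------------------------------------------------------------

def chamfer(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Symmetric squared chamfer: mean_A min_B ||.||^2 + mean_B min_A ||.||^2."""
    a = np.asarray(points_a, dtype=np.float64)
    b = np.asarray(points_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("chamfer distance of an empty set")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float((d_ab ** 2).mean() + (d_ba ** 2).mean())


def chamfer_t(verts: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Differentiable chamfer between decoded vertices and target points.

    Nearest-neighbor assignments are computed outside the graph (piecewise
    constant), the distances themselves inside it.
    """
    target = np.asarray(target, dtype=np.float32)
    idx_vt = cKDTree(target).query(verts.data)[1]
    idx_tv = cKDTree(verts.data).query(target)[1]
    d1 = ((verts - nn.Tensor(target[idx_vt])) ** 2.0).sum(axis=-1).mean()
    d2 = ((verts[idx_tv] - nn.Tensor(target)) ** 2.0).sum(axis=-1).mean()
    return d1 + d2


# ---------------------------------------------------------------------------
# Mesh regularizers
# ---------------------------------------------------------------------------

class MeshTopology:
    """Precomputed constants of the template connectivity."""

    def __init__(self, faces: np.ndarray, n_vertices: int):
        self.faces = np.asarray(faces)
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2),
                        axis=1)
        self.edges = np.unique(edges, axis=0)
        # adjacent face pairs via shared edges
        edge_key = {}
        pairs = []
        for fi, face in enumerate(self.faces):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = (min(face[a], face[b]), max(face[a], face[b]))
                if key in edge_key:
                    pairs.append((edge_key[key], fi))
                else:
                    edge_key[key] = fi
        self.face_pairs = np.asarray(pairs, dtype=np.int64)
        # row-normalized uniform adjacency for the graph Laplacian
        adj = np.zeros((n_vertices, n_vertices), dtype=np.float32)
        adj[self.edges[:, 0], self.edges[:, 1]] = 1.0
        adj[self.edges[:, 1], self.edges[:, 0]] = 1.0
        deg = np.maximum(adj.sum(axis=1, keepdims=True), 1.0)
        self.adj_norm = adj / deg


def _cross(u: nn.Tensor, v: nn.Tensor) -> nn.Tensor:
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    return nn.stack([uy * vz - uz * vy, uz * vx - ux * vz,
                     ux * vy - uy * vx], axis=1)


def mesh_regularizers(verts: nn.Tensor, topo: MeshTopology):
    """(NC, EL, LS) as differentiable scalars; all mean-normalized.

    NC: mean over adjacent-face pairs of 1 - cos(angle of face normals).
    EL: mean squared edge length.
    LS: mean squared norm of the uniform graph Laplacian of the vertices.
    """
    f = topo.faces
    a, b, c = verts[f[:, 0]], verts[f[:, 1]], verts[f[:, 2]]
    normals = _cross(b - a, c - a)
    norm2 = (normals * normals).sum(axis=-1)
    eps = 1e-12
    n1 = normals[topo.face_pairs[:, 0]]
    n2 = normals[topo.face_pairs[:, 1]]
    cos = (n1 * n2).sum(axis=-1) * (
        ((norm2[topo.face_pairs[:, 0]] + eps)
         * (norm2[topo.face_pairs[:, 1]] + eps)) ** -0.5)
    nc = (1.0 - cos).mean()
    e = verts[topo.edges[:, 0]] - verts[topo.edges[:, 1]]
    el = (e * e).sum(axis=-1).mean()
    lap = nn.Tensor(topo.adj_norm) @ verts - verts
    ls = (lap * lap).sum(axis=-1).mean()
    return nc, el, ls


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class PCAEConfig:
    n_points: int = 2048
    latent: int = 512
    w_cd: float = 1.0
    w_nc: float = 0.1
    w_el: float = 1.0
    w_ls: float = 0.1
    steps: int = 2000
    lr: float = 1e-3
    weight_decay: float = 1e-5
    floor_factor: float = 0.05
    sigma_pad: float = 0.05
    knn_k: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if min(self.w_cd, self.w_nc, self.w_el, self.w_ls) < 0:
            raise ValueError("loss weights must be non-negative")


class PCAE(nn.Module):
    """EdgeConv encoder -> z (512) -> two-step residual template deformation."""

    def __init__(self, n_points: int = 2048, latent: int = 512,
                 knn_k: int = 20, ec_widths=(64, 128, 256),
                 pre_latent: int = 576, dec_hidden: int = 416):
        super().__init__()
        self.n_points = n_points
        self.latent = latent
        self.knn_k = knn_k
        self.template = make_template(n_points)
        self.topology = MeshTopology(self.template.faces,
                                     self.template.n_vertices)
        self.ec1 = EdgeConv(3, ec_widths[0])
        self.ec2 = EdgeConv(ec_widths[0], ec_widths[1])
        self.ec3 = EdgeConv(ec_widths[1], ec_widths[2])
        self.pre_pool = nn.mlp([sum(ec_widths), pre_latent])
        self.to_latent = nn.Linear(pre_latent, latent)
        d = dec_hidden
        self.f1 = nn.Sequential(nn.Linear(latent + 3, d), nn.ReLU(),
                                nn.Linear(d, d), nn.ReLU(), nn.Linear(d, 3))
        self.f2 = nn.Sequential(nn.Linear(latent + 3, d), nn.ReLU(),
                                nn.Linear(d, d), nn.ReLU(), nn.Linear(d, 3))

    def encode(self, points: np.ndarray) -> nn.Tensor:
        pts = np.asarray(points, dtype=np.float32)
        if len(pts) != self.n_points:
            raise ValueError(
                f"encoder expects exactly {self.n_points} points, "
                f"got {len(pts)}; apply fps/pad_cloud first")
        nbr = knn_graph(pts, self.knn_k).neighbors
        x = nn.Tensor(pts)
        h1 = self.ec1(x, nbr)
        h2 = self.ec2(h1, nbr)
        h3 = self.ec3(h2, nbr)
        h = self.pre_pool(nn.concat([h1, h2, h3], axis=-1))
        return self.to_latent(h.max(axis=0))

    def decode(self, z: nn.Tensor) -> nn.Tensor:
        """Latent code -> deformed template vertices (M, 3)."""
        m = self.template.n_vertices
        z_rep = z.reshape(1, -1).broadcast_to((m, self.latent))
        v0 = nn.Tensor(self.template.vertices.astype(np.float32))
        v1 = v0 + self.f1(nn.concat([z_rep, v0], axis=-1))
        v2 = v1 + self.f2(nn.concat([z_rep, v1], axis=-1))
        return v2

    def forward(self, points: np.ndarray) -> nn.Tensor:
        return self.decode(self.encode(points))

    def decoded_mesh(self, points: np.ndarray) -> trimesh.Trimesh:
        with nn.no_grad():
            verts = self.forward(points)
        return trimesh.Trimesh(vertices=verts.data.astype(np.float64),
                               faces=self.template.faces, process=False)


def build_pcae(cfg: PCAEConfig | None = None, seed: int | None = None,
               **kwargs) -> PCAE:
    cfg = cfg or PCAEConfig()
    if seed is not None:
        nn.manual_seed(seed)
    return PCAE(n_points=cfg.n_points, latent=cfg.latent, knn_k=cfg.knn_k,
                **kwargs)


def pcae_loss(verts: nn.Tensor, target_points: np.ndarray, topo: MeshTopology,
              cfg: PCAEConfig) -> nn.Tensor:
    """w_cd*CD(vertices, targets) + w_nc*NC + w_el*EL + w_ls*LS."""
    cd = chamfer_t(verts, target_points)
    nc, el, ls = mesh_regularizers(verts, topo)
    return (cfg.w_cd * cd + cfg.w_nc * nc + cfg.w_el * el + cfg.w_ls * ls)


def train_pcae(model: PCAE, gt_meshes, cfg: PCAEConfig):
    """Fit the autoencoder to point clouds sampled from ground-truth meshes.

    All fissure classes are pooled: the model learns one shape space for
    every fissure.  Per step, one mesh is drawn, N points are sampled
    area-weighted from its surface, and the regularized mesh loss is
    minimized with Adam under the cosine schedule.
    """
    from .metrics import sample_surface

    meshes = [m for m in gt_meshes if m is not None and len(m.faces)]
    if not meshes:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr,
                  weight_decay=cfg.weight_decay)
    sched = nn.CosineAnnealing(opt, cfg.steps, cfg.floor_factor)
    history = []
    model.train()
    for step in range(cfg.steps):
        sched.step(step)
        mesh = meshes[rng.integers(len(meshes))]
        target = sample_surface(mesh, cfg.n_points,
                                seed=int(rng.integers(2 ** 31)))
        verts = model(target)
        loss = pcae_loss(verts, target, model.topology, cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return model, history


def reconstruct_with_pcae(point_sets, model: PCAE, cfg: PCAEConfig):
    """One forward pass per fissure; fps/pad to N points; empty -> n.a."""
    meshes, na = [], []
    model.eval()
    for i, pts in enumerate(point_sets):
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
        if len(pts) == 0:
            meshes.append(None)
            na.append(True)
            continue
        if len(pts) > cfg.n_points:
            pts = pts[fps(pts, cfg.n_points)]
        elif len(pts) < cfg.n_points:
            pts = pad_cloud(pts, cfg.n_points, cfg.sigma_pad,
                            seed=cfg.seed + i)
        meshes.append(model.decoded_mesh(pts))
        na.append(False)
    return meshes, na


def save_pcae(model: PCAE, path, extra: dict | None = None):
    import json

    meta = {"n_points": model.n_points, "latent": model.latent,
            "knn_k": model.knn_k}
    meta.update(extra or {})
    np.savez(path, __meta__=json.dumps(meta),
             **{f"param/{k}": v for k, v in model.state_dict().items()})


def load_pcae(path) -> PCAE:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model = PCAE(n_points=meta["n_points"], latent=meta["latent"],
                 knn_k=meta["knn_k"])
    model.load_state_dict(state)
    return model
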