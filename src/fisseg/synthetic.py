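"""Synthetic toy lung cases with analytic fissure sheets.

Each case contains two ellipsoidal "lungs" inside a CT-like volume.  A
fissure is modelled as a low-order polynomial height field

    z = a + b (x-cx) + c (y-cy) + d (x-cx)^2 + e (y-cy)^2 + f (x-cx)(y-cy)

clipped to its lung: one oblique sheet in the left lung (class 1), an
oblique and a horizontal sheet in the right lung (classes 2 and 3, kept
non-intersecting).  The image shows lung parenchyma around -850 HU with
Gaussian noise, a bright ridge of Gaussian cross-profile along every sheet
(fissures appear as thin bright sheets in CT) and a few ellipsoidal
distractor blobs.  Ground-truth meshes are triangulated directly from the
analytic height fields, so the geometric reference is exact rather than a
product of the voxelized label map.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .imaging import Volume, voxel_to_norm

LABEL_NAMES = ("background", "left_oblique", "right_oblique",
               "right_horizontal")


@dataclass
class SynthParams:
    """Generator appearance/geometry parameters (HU and voxel units)."""

    lung_hu: float = -850.0
    outside_hu: float = 40.0
    noise_sigma: float = 40.0
    ridge_amp: float = 300.0
    ridge_width: float = 1.0
    n_distractors: int = 3
    distractor_amp: float = 250.0
    label_halfwidth: float = 0.5
    #: sheets cover only the inner part of the lung footprint (squared
    #: fractional radius), keeping the labeled fraction in the thin-structure
    #: regime (< 2 % of lung voxels)
    sheet_extent: float = 0.4


@dataclass
class Sheet:
    """Analytic height field z = f(x, y) clipped to one lung ellipsoid."""

    coeffs: np.ndarray            # (a, b, c, d, e, f)
    center_xy: np.ndarray         # expansion point (cx, cy) in voxels
    semi_xy: np.ndarray           # lung semi-axes in x, y (voxels)
    extent: float                 # squared fractional footprint radius
    lung: int                     # 0 = left, 1 = right
    label: int                    # 1..3

    def in_footprint(self, x, y):
        dx = (np.asarray(x, dtype=np.float64) - self.center_xy[0]) / self.semi_xy[0]
        dy = (np.asarray(y, dtype=np.float64) - self.center_xy[1]) / self.semi_xy[1]
        return dx ** 2 + dy ** 2 <= self.extent

    def height(self, x, y):
        a, b, c, d, e, f = self.coeffs
        dx = np.asarray(x, dtype=np.float64) - self.center_xy[0]
        dy = np.asarray(y, dtype=np.float64) - self.center_xy[1]
        return a + b * dx + c * dy + d * dx ** 2 + e * dy ** 2 + f * dx * dy


@dataclass
class SyntheticCase:
    volume: Volume
    lung_mask: np.ndarray
    labels: np.ndarray
    gt_meshes: list                      # 3 trimesh.Trimesh, normalized coords
    sheets: list = field(default_factory=list)
    ellipsoids: list = field(default_factory=list)   # (center, semi) pairs
    seed: int = 0
    params: SynthParams = field(default_factory=SynthParams)


def _ellipsoid_field(shape, center, semi):
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                        indexing="ij")
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return q


def _triangulate_sheet(sheet: Sheet, center, semi, shape):
    """Exact mesh of the height field where it lies inside the ellipsoid."""
    x0, x1 = int(np.floor(center[0] - semi[0])), int(np.ceil(center[0] + semi[0]))
    y0, y1 = int(np.floor(center[1] - semi[1])), int(np.ceil(center[1] + semi[1]))
    xs = np.arange(max(x0, 0), min(x1, shape[0] - 1) + 1)
    ys = np.arange(max(y0, 0), min(y1, shape[1] - 1) + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = sheet.height(gx, gy)
    inside = (((gx - center[0]) / semi[0]) ** 2
              + ((gy - center[1]) / semi[1]) ** 2
              + ((gz - center[2]) / semi[2]) ** 2) <= 1.0
    inside &= sheet.in_footprint(gx, gy)
    inside &= (gz >= 0) & (gz <= shape[2] - 1)
    vid = -np.ones(gx.shape, dtype=np.int64)
    vid[inside] = np.arange(int(inside.sum()))
    verts_vox = np.stack([gx[inside], gy[inside], gz[inside]], axis=1)
    faces = []
    for i in range(gx.shape[0] - 1):
        for j in range(gx.shape[1] - 1):
            c00, c10 = vid[i, j], vid[i + 1, j]
            c01, c11 = vid[i, j + 1], vid[i + 1, j + 1]
            if min(c00, c10, c01, c11) >= 0:
                faces.append((c00, c10, c11))
                faces.append((c00, c11, c01))
    if not faces:
        raise RuntimeError("degenerate synthetic sheet (empty mesh)")
    verts = voxel_to_norm(verts_vox, shape)
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)


def generate_case(seed: int, size=(64, 64, 64),
                  params: SynthParams | None = None) -> SyntheticCase:
    """Generate one reproducible toy case (volume, mask, labels, meshes)."""
    size = tuple(int(s) for s in size)
    if any(s < 32 for s in size):
        raise ValueError("size must be at least 32 voxels per axis")
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    nx, ny, nz = size

    ellipsoids = []
    for fx in (0.28, 0.72):
        center = np.array([fx * nx, 0.5 * ny, 0.5 * nz])
        center += rng.uniform(-0.015, 0.015, 3) * np.array(size)
        semi = (np.array([0.16 * nx, 0.30 * ny, 0.36 * nz])
                * rng.uniform(0.95, 1.05, 3))
        ellipsoids.append((center, semi))

    def make_sheet(lung, label, z_frac, tilt_range):
        center, semi = ellipsoids[lung]
        a = center[2] + z_frac * semi[2]
        b = rng.uniform(*tilt_range) * rng.choice([-1, 1])
        c = rng.uniform(-0.2, 0.2)
        d, e, f = rng.uniform(-0.01, 0.01, 3)
        return Sheet(np.array([a, b, c, d, e, f]), center[:2].copy(),
                     semi[:2].copy(), params.sheet_extent, lung, label)

    sheets = [
        make_sheet(0, 1, rng.uniform(-0.1, 0.1), (0.2, 0.45)),
        make_sheet(1, 2, rng.uniform(-0.35, -0.2), (0.2, 0.4)),
        make_sheet(1, 3, rng.uniform(0.3, 0.45), (0.02, 0.1)),
    ]
    # keep the two right-lung sheets separated by at least 3 voxels
    center, semi = ellipsoids[1]
    xs = np.arange(int(center[0] - semi[0]), int(center[0] + semi[0]) + 1)
    ys = np.arange(int(center[1] - semi[1]), int(center[1] + semi[1]) + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    footprint = (((gx - center[0]) / semi[0]) ** 2
                 + ((gy - center[1]) / semi[1]) ** 2) <= 1.0
    gap = (sheets[2].height(gx, gy) - sheets[1].height(gx, gy))[footprint]
    if gap.size and gap.min() < 3.0:
        sheets[2].coeffs[0] += 3.0 - gap.min()

    mask = np.zeros(size, dtype=bool)
    fields = []
    for center, semi in ellipsoids:
        q = _ellipsoid_field(size, center, semi)
        fields.append(q)
        mask |= q <= 1.0

    vox = np.full(size, params.outside_hu, dtype=np.float32)
    vox[mask] = params.lung_hu
    vox += rng.normal(0.0, params.noise_sigma, size).astype(np.float32)

    zs = np.arange(nz, dtype=np.float64)
    labels = np.zeros(size, dtype=np.uint8)
    for sheet in sheets:
        center, semi = ellipsoids[sheet.lung]
        gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        f = sheet.height(gx, gy)                       # (nx, ny)
        dz = zs[None, None, :] - f[:, :, None]         # signed vertical dist
        in_sheet = (fields[sheet.lung] <= 1.0) \
            & sheet.in_footprint(gx, gy)[:, :, None]
        ridge = params.ridge_amp * np.exp(
            -0.5 * (dz / params.ridge_width) ** 2)
        vox += np.where(in_sheet, ridge, 0.0).astype(np.float32)
        near = np.abs(dz) <= params.label_halfwidth
        labels[near & in_sheet] = sheet.label

    lung_idx = np.argwhere(mask)
    for _ in range(params.n_distractors):
        c = lung_idx[rng.integers(len(lung_idx))].astype(np.float64)
        s = rng.uniform(1.5, 3.5, 3)
        blob = _ellipsoid_field(size, c, s) <= 1.0
        vox[blob] += params.distractor_amp

    gt_meshes = [
        _triangulate_sheet(sh, *ellipsoids[sh.lung], size) for sh in sheets
    ]
    return SyntheticCase(Volume(vox), mask, labels, gt_meshes,
                         sheets, ellipsoids, seed, params)


def label_points(case: SyntheticCase, voxel_indices: np.ndarray,
                 threshold: float = 1.0) -> np.ndarray:
    """Nearest-sheet class per point within `threshold` voxels, else 0.

    Distance is the vertical offset to the analytic height field, evaluated
    only for points inside the sheet's lung.
    """
    idx = np.atleast_2d(np.asarray(voxel_indices))
    out = np.zeros(len(idx), dtype=np.int64)
    best = np.full(len(idx), np.inf)
    x, y, z = idx[:, 0].astype(float), idx[:, 1].astype(float), idx[:, 2]
    for sheet in case.sheets:
        center, semi = case.ellipsoids[sheet.lung]
        in_lung = (((x - center[0]) / semi[0]) ** 2
                   + ((y - center[1]) / semi[1]) ** 2
                   + ((z - center[2]) / semi[2]) ** 2) <= 1.0
        in_lung &= sheet.in_footprint(x, y)
        dist = np.abs(z - sheet.height(x, y))
        hit = in_lung & (dist <= threshold) & (dist < best)
        out[hit] = sheet.label
        best[hit] = dist[hit]
    return out


def uniform_keypoints(case: SyntheticCase, k_max: int, seed: int):
    """Uniformly sampled lung voxels as a dense keypoint abstraction.

    At desk scale (64^3 toy volumes) the sparse detectors return far fewer
    candidates than at clinical resolution; a uniform sample inside the
    lung mask provides a keypoint cloud of controllable density with the
    same interface (normalized coordinates + intensity-patch features).
    """
    from .imaging import normalize_intensity, extract_patch_features
    from .keypoints import KeypointCloud

    rng = np.random.default_rng(seed)
    lung_idx = np.argwhere(case.lung_mask)
    k = min(k_max, len(lung_idx))
    sel = rng.choice(len(lung_idx), size=k, replace=False)
    idx = lung_idx[np.sort(sel)]
    norm = normalize_intensity(case.volume)
    return KeypointCloud(voxel_to_norm(idx, case.lung_mask.shape), idx,
                         extract_patch_features(norm, idx), "uniform")


def make_dataset(n_cases: int, seed: int, size=(64, 64, 64),
                 k_max: int = 8192, kp_source: str = "uniform",
                 params: SynthParams | None = None,
                 label_threshold: float = 1.0):
    """Cases plus point-labeled keypoint clouds.

    ``kp_source`` selects the cloud: "uniform" (dense, default — stands in
    for the 20 000-point clouds the detectors produce at clinical
    resolution) or "foerstner" (the actual operator; sparse at toy scale).
    Point labels come from nearest-sheet assignment within
    ``label_threshold`` voxels.  Returns ``(case, cloud, labels)`` triples.
    """
    from .keypoints import foerstner_keypoints

    if n_cases < 1:
        raise ValueError("need at least one case")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases)
    out = []
    for s in child_seeds:
        case_seed = int(s) % (2 ** 31)
        case = generate_case(case_seed, size, params)
        if kp_source == "uniform":
            cloud = uniform_keypoints(case, k_max, case_seed + 1)
        elif kp_source == "foerstner":
            cloud = foerstner_keypoints(case.volume, case.lung_mask,
                                        k_max=k_max)
        else:
            raise ValueError(f"unknown kp_source {kp_source!r}")
        y = label_points(case, cloud.voxel_indices, label_threshold)
        out.append((case, cloud, y))
    return out


def train_test_split(items, n_train: int):
    return items[:n_train], items[n_train:]
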