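"""Dense surface reconstruction from sparse fissure point clouds.

The chain mirrors the classical route: PCA normal estimation with
minimum-spanning-tree sign propagation, Poisson surface reconstruction of
the (watertight) indicator iso-surface, then clipping to the lung mask and
keeping the largest face-connected component, which opens the surface at
the fissure boundary.

The Poisson solve runs on a regular grid of resolution 2**depth: oriented
normals are splatted trilinearly into a vector field, lightly smoothed,
and the indicator is recovered from the field's divergence with a DCT-based
Neumann Poisson solver.  The iso-level is the mean indicator value at the
input samples; marching cubes extracts the mesh.

Ground-truth meshes from voxel label maps use topology-preserving binary
thinning (medial surface) before the same normal + Poisson chain, or the
faster alternative of randomly sampling fissure voxels directly.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import fft as sfft
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from .imaging import norm_to_voxel, voxel_to_norm

MIN_POISSON_POINTS = 50


class ReconstructionError(RuntimeError):
    """Raised when a surface cannot be reconstructed from the input."""


# ---------------------------------------------------------------------------
# Oriented normals
# ---------------------------------------------------------------------------

def estimate_oriented_normals(points: np.ndarray, k_n: int = 30):
    """PCA normals with globally consistent signs.

    Per point, the normal is the smallest-eigenvalue eigenvector of the
    covariance over its k_n nearest neighbors.  Signs are made coherent by
    propagating flips along a minimum spanning tree of the kNN graph
    weighted by 1 - |n_i . n_j|.
    Returns ``(points, unit_normals)``.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points for normal estimation")
    k = int(min(k_n, n - 1))
    if k < 2:
        raise ValueError("k_n too small")
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k + 1)
    nbr = nbr[:, 1:]
    local = pts[nbr] - pts[:, None, :]
    cov = np.einsum("nki,nkj->nij", local, local) / k
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    w = 1.0 - np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    graph = coo_matrix((w + 1e-9, (rows, cols)), shape=(n, n))
    graph = graph.minimum(graph.T) + graph.maximum(graph.T)  # symmetrize
    mst = minimum_spanning_tree(graph)
    mst = mst + mst.T
    order, pred = breadth_first_order(mst, 0, directed=False)
    for node in order[1:]:
        p = pred[node]
        if np.dot(normals[node], normals[p]) < 0:
            normals[node] = -normals[node]
    return pts, normals


# ---------------------------------------------------------------------------
# Poisson surface reconstruction on a regular grid
# ---------------------------------------------------------------------------

def _solve_poisson_neumann(rhs: np.ndarray) -> np.ndarray:
    """Solve lap(x) = rhs with homogeneous Neumann BC via DCT-II."""
    res = rhs.shape
    rhat = sfft.dctn(rhs, type=2, norm="ortho")
    eig = sum(
        (2.0 * np.cos(np.pi * np.arange(res[d]) / res[d]) - 2.0).reshape(
            [-1 if i == d else 1 for i in range(3)])
        for d in range(3))
    eig_flat = eig.copy()
    eig_flat[0, 0, 0] = 1.0
    xhat = rhat / eig_flat
    xhat[0, 0, 0] = 0.0
    return sfft.idctn(xhat, type=2, norm="ortho")


def _trilinear_splat(grid: np.ndarray, pos: np.ndarray, values: np.ndarray):
    """Scatter-add `values` (n, C) at fractional positions into grid (C-last)."""
    base = np.floor(pos).astype(np.int64)
    frac = pos - base
    res = grid.shape[:3]
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wx = frac[:, 0] if dx else 1 - frac[:, 0]
                wy = frac[:, 1] if dy else 1 - frac[:, 1]
                wz = frac[:, 2] if dz else 1 - frac[:, 2]
                wgt = wx * wy * wz
                ix = np.clip(base[:, 0] + dx, 0, res[0] - 1)
                iy = np.clip(base[:, 1] + dy, 0, res[1] - 1)
                iz = np.clip(base[:, 2] + dz, 0, res[2] - 1)
                np.add.at(grid, (ix, iy, iz),
                          values * wgt[:, None])


def _trilinear_sample(field: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(field, pos.T, order=1, mode="nearest")


def poisson_reconstruct(points: np.ndarray, normals: np.ndarray,
                        depth: int = 6,
                        smooth_sigma: float = 1.3) -> trimesh.Trimesh:
    """Watertight indicator iso-surface from an oriented point cloud.

    `depth` sets the grid resolution to 2**depth per axis (the analogue of
    the octree depth of adaptive solvers).
    """
    pts = np.asarray(points, dtype=np.float64)
    nrm = np.asarray(normals, dtype=np.float64)
    if len(pts) < MIN_POISSON_POINTS:
        raise ReconstructionError(
            f"need at least {MIN_POISSON_POINTS} points, got {len(pts)}")
    res = 2 ** int(depth)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = hi - lo
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):  # rank < 2: collinear input
        raise ReconstructionError("degenerate (collinear) point cloud")
    margin = 6.0
    scale = (res - 1 - 2 * margin) / max(extent.max(), 1e-12)
    to_grid = lambda p: (p - (lo + hi) / 2) * scale + (res - 1) / 2.0

    gpts = to_grid(pts)
    field = np.zeros((res, res, res, 3))
    _trilinear_splat(field, gpts, nrm)
    for c in range(3):
        field[..., c] = ndimage.gaussian_filter(field[..., c], smooth_sigma)
    div = np.zeros((res, res, res))
    for c in range(3):
        div += np.gradient(field[..., c], axis=c)
    chi = _solve_poisson_neumann(div)
    iso = float(np.mean(_trilinear_sample(chi, gpts)))
    lo_c, hi_c = chi.min(), chi.max()
    if not lo_c < iso < hi_c:
        raise ReconstructionError("indicator iso-level outside field range")
    verts, faces, _, _ = skmeasure.marching_cubes(chi, level=iso)
    verts = (verts - (res - 1) / 2.0) / scale + (lo + hi) / 2
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if len(mesh.faces) == 0:
        raise ReconstructionError("empty reconstruction")
    return mesh


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def clip_and_largest_component(mesh: trimesh.Trimesh, mask: np.ndarray,
                               shape=None) -> trimesh.Trimesh | None:
    """Drop faces with any vertex outside the mask, keep the biggest patch.

    Mesh vertices are in normalized coordinates; `mask` is the voxel lung
    mask (`shape` defaults to the mask's).  Returns None when nothing
    survives (the n.a. pathway).
    """
    mask = np.asarray(mask, dtype=bool)
    shape = shape or mask.shape
    verts = np.asarray(mesh.vertices)
    vox = norm_to_voxel(np.clip(verts, -1, 1), shape)
    inside_box = np.all(np.abs(verts) <= 1.0, axis=1)
    inside = inside_box & mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    keep_faces = inside[np.asarray(mesh.faces)].all(axis=1)
    if not keep_faces.any():
        return None
    sub = trimesh.Trimesh(vertices=verts,
                          faces=np.asarray(mesh.faces)[keep_faces],
                          process=False)
    labels = trimesh.graph.connected_component_labels(sub.face_adjacency,
                                                      node_count=len(sub.faces))
    counts = np.bincount(labels)
    best = int(np.argmax(counts))  # argmax ties -> lowest label index
    comp = trimesh.Trimesh(vertices=sub.vertices,
                           faces=sub.faces[labels == best],
                           process=False)
    comp.remove_unreferenced_vertices()
    return comp


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges referenced by exactly one face (open-surface test)."""
    edges = np.sort(np.asarray(mesh.edges), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


_S26 = np.ones((3, 3, 3), dtype=bool)
_S6 = ndimage.generate_binary_structure(3, 1)
_N18 = ndimage.generate_binary_structure(3, 2)
_FACE_NBRS = [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]


def _is_simple(nb: np.ndarray) -> bool:
    """26/6 simple-point test on a 3x3x3 neighborhood (center foreground).

    Deleting the center preserves local topology iff exactly one
    26-component of foreground remains in the neighborhood and exactly one
    6-component of background in the 18-neighborhood touches the center's
    faces (Malandain-Bertrand characterization).
    """
    fg = nb.copy()
    fg[1, 1, 1] = False
    if not fg.any():
        return False  # isolated voxel: deletion removes a component
    _, n_fg = ndimage.label(fg, structure=_S26)
    if n_fg != 1:
        return False
    bg = ~nb & _N18
    bg[1, 1, 1] = False
    lab, _ = ndimage.label(bg, structure=_S6)
    touched = {lab[p] for p in _FACE_NBRS if lab[p] > 0}
    return len(touched) == 1


def _is_surface_point(nb: np.ndarray) -> bool:
    """Both 6-neighbors background along some axis: part of a thin sheet
    (or curve/point), protected from deletion."""
    return ((not nb[0, 1, 1] and not nb[2, 1, 1])
            or (not nb[1, 0, 1] and not nb[1, 2, 1])
            or (not nb[1, 1, 0] and not nb[1, 1, 2]))


_DIRECTIONS = [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0),
               (1, 0, 0), (-1, 0, 0)]


def binary_thinning(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning toward a one-voxel-thick medial surface.

    Iterates over the six face directions; in each sub-iteration, border
    voxels in that direction are deleted sequentially (lexicographic order)
    when they are simple points and not surface points.  Runs to fixpoint;
    output is a subset of the input, idempotent, and preserves the
    26-connected component count.
    """
    out = np.pad(np.asarray(binary, dtype=bool), 1)
    if not out.any():
        return np.asarray(binary, dtype=bool).copy()
    changed = True
    while changed:
        changed = False
        for d in _DIRECTIONS:
            # neighbor in direction d is background: roll by -d aligns
            # out[p + d] with position p
            border = out & ~np.roll(out, tuple(-c for c in d), axis=(0, 1, 2))
            for x, y, z in np.argwhere(border):
                nb = out[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2]
                if not nb[1, 1, 1] or _is_surface_point(nb):
                    continue
                if _is_simple(nb):
                    out[x, y, z] = False
                    changed = True
    return out[1:-1, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# End-to-end reconstruction chains
# ---------------------------------------------------------------------------

def reconstruct_fissure(points: np.ndarray, mask: np.ndarray,
                        depth: int = 6, k_n: int = 30):
    """normals -> Poisson -> clip for one fissure; None on failure (n.a.)."""
    if points is None or len(points) < MIN_POISSON_POINTS:
        return None
    try:
        pts, normals = estimate_oriented_normals(points, k_n)
        mesh = poisson_reconstruct(pts, normals, depth=depth)
    except (ReconstructionError, ValueError):
        return None
    return clip_and_largest_component(mesh, mask)


def reconstruct_from_segmentation(point_sets, mask: np.ndarray,
                                  depth: int = 6, k_n: int = 30):
    """Per-fissure reconstruction from segmented (normalized) point sets.

    Returns ``(meshes, na_flags)`` with one entry per fissure class 1..3.
    """
    meshes, na = [], []
    for pts in point_sets:
        mesh = reconstruct_fissure(pts, mask, depth=depth, k_n=k_n)
        meshes.append(mesh)
        na.append(mesh is None)
    return meshes, na


def labelmap_to_meshes(labels: np.ndarray, mask: np.ndarray,
                       mode: str = "thinning", seed: int = 0,
                       n_sample: int = 10_000, depth: int = 6,
                       k_n: int = 30):
    """Fissure meshes from a 4-class voxel label map.

    mode="thinning": medial-surface thinning of each class mask, voxel
    centers as the point cloud.  mode="sample10k": skip thinning and sample
    up to `n_sample` class voxels uniformly (seeded).
    """
    if mode not in ("thinning", "sample10k"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    meshes, na = [], []
    for cls in (1, 2, 3):
        cls_mask = labels == cls
        if not cls_mask.any():
            meshes.append(None)
            na.append(True)
            continue
        if mode == "thinning":
            idx = np.argwhere(binary_thinning(cls_mask))
        else:
            idx = np.argwhere(cls_mask)
            if len(idx) > n_sample:
                keep = rng.choice(len(idx), size=n_sample, replace=False)
                idx = idx[np.sort(keep)]
        pts = voxel_to_norm(idx, labels.shape)
        mesh = reconstruct_fissure(pts, mask, depth=depth, k_n=k_n)
        meshes.append(mesh)
        na.append(mesh is None)
    return meshes, na


FISSURE_FILES = ("fissure_LO.ply", "fissure_RO.ply", "fissure_RH.ply")


def save_meshes(meshes, na_flags, out_dir, frame: str = "normalized"):
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    for mesh, name in zip(meshes, FISSURE_FILES):
        if mesh is not None:
            mesh.export(os.path.join(out_dir, name))
    with open(os.path.join(out_dir, "meshes.json"), "w") as fh:
        json.dump({"frame": frame, "na": list(map(bool, na_flags)),
                   "files": list(FISSURE_FILES)}, fh, indent=2)
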