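"""Surface-distance evaluation between triangle meshes.

Distances follow the pooled symmetric convention: both surfaces are sampled
uniformly by area, every sample is measured by its *exact* point-to-triangle
distance to the other mesh, and the two directed sample sets are pooled.
ASSD is the pooled mean, SDSD the pooled standard deviation, HD the pooled
maximum.  A missing (empty) prediction produces a non-assigned (n.a.)
report rather than an error; aggregates skip n.a. entries.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .imaging import Volume, norm_to_world


@dataclass
class DistanceReport:
    assd: float | None
    sdsd: float | None
    hd: float | None
    na: bool = False
    n_points_used: int = 0


def sample_surface(mesh: trimesh.Trimesh, n: int, seed: int = 0) -> np.ndarray:
    """Area-weighted uniform samples, barycentric within faces, seeded."""
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("cannot sample an empty mesh")
    rng = np.random.default_rng(seed)
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    u, v, w = 1.0 - r1, r1 * (1.0 - r2), r1 * r2
    tri = mesh.vertices[mesh.faces[face_idx]]
    return (u[:, None] * tri[:, 0] + v[:, None] * tri[:, 1]
            + w[:, None] * tri[:, 2])


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point on each paired triangle (Ericson's region test)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.nan_to_num(d1 / (d1 - d3))
        t_ac = np.nan_to_num(d2 / (d2 - d6))
        t_bc = np.nan_to_num((d4 - d3) / ((d4 - d3) + (d5 - d6)))
        denom = va + vb + vc
        v_in = np.nan_to_num(vb / denom)
        w_in = np.nan_to_num(vc / denom)

    q = a + v_in[:, None] * ab + w_in[:, None] * ac           # interior
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)           # edge BC
    q[m] = b[m] + t_bc[m, None] * (c[m] - b[m])
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)                     # edge AC
    q[m] = a[m] + t_ac[m, None] * ac[m]
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)                     # edge AB
    q[m] = a[m] + t_ab[m, None] * ab[m]
    m = (d6 >= 0) & (d5 <= d6)                                # vertex C
    q[m] = c[m]
    m = (d3 >= 0) & (d4 <= d3)                                # vertex B
    q[m] = b[m]
    m = (d1 <= 0) & (d2 <= 0)                                 # vertex A
    q[m] = a[m]
    return q


def point_mesh_distance(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface.

    A nearest-vertex upper bound prunes candidate triangles (via a centroid
    KD-tree) without losing exactness.
    """
    points = np.asarray(points, dtype=np.float64)
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces)
    tri = verts[faces]
    centroids = tri.mean(axis=1)
    radius = np.linalg.norm(tri - centroids[:, None], axis=2).max(axis=1)
    r_max = radius.max()
    d_up = cKDTree(verts).query(points)[0]
    cent_tree = cKDTree(centroids)
    groups = cent_tree.query_ball_point(points, d_up + r_max + 1e-12)
    counts = np.fromiter((len(g) for g in groups), dtype=np.int64,
                         count=len(groups))
    pt_idx = np.repeat(np.arange(len(points)), counts)
    tri_idx = np.concatenate([np.asarray(g, dtype=np.int64) for g in groups]) \
        if counts.sum() else np.zeros(0, dtype=np.int64)
    q = _closest_point_on_triangles(points[pt_idx], tri[tri_idx])
    d_pair = np.linalg.norm(points[pt_idx] - q, axis=1)
    out = d_up.copy()  # nearest-vertex distance is always attainable
    np.minimum.at(out, pt_idx, d_pair)
    return out


def surface_distances(mesh_a, mesh_b, n: int = 10_000,
                      seed: int = 0) -> DistanceReport:
    """Pooled symmetric surface distances between two meshes."""
    if (mesh_a is None or mesh_b is None
            or len(mesh_a.faces) == 0 or len(mesh_b.faces) == 0):
        return DistanceReport(None, None, None, na=True)
    pa = sample_surface(mesh_a, n, seed)
    pb = sample_surface(mesh_b, n, seed + 1)
    d = np.concatenate([point_mesh_distance(pa, mesh_b),
                        point_mesh_distance(pb, mesh_a)])
    return DistanceReport(float(d.mean()), float(d.std()), float(d.max()),
                          na=False, n_points_used=2 * n)


def evaluate_case(pred_meshes, gt_meshes, n: int = 10_000, seed: int = 0):
    """Per-fissure reports plus the case's non-assigned count.

    `pred_meshes` may contain None (or empty meshes) for fissures with no
    segmented points.  Aggregate means are over non-n.a. fissures only.
    """
    reports = [surface_distances(p, g, n=n, seed=seed + i)
               for i, (p, g) in enumerate(zip(pred_meshes, gt_meshes))]
    na_count = sum(r.na for r in reports)
    valid = [r for r in reports if not r.na]
    aggregate = {
        "assd": float(np.mean([r.assd for r in valid])) if valid else None,
        "sdsd": float(np.mean([r.sdsd for r in valid])) if valid else None,
        "hd": float(np.mean([r.hd for r in valid])) if valid else None,
        "n_valid": len(valid),
    }
    return reports, na_count, aggregate


def mesh_in_world(mesh: trimesh.Trimesh, vol: Volume) -> trimesh.Trimesh:
    """Convert a mesh from normalized coordinates to physical mm."""
    verts = norm_to_world(np.asarray(mesh.vertices), vol)
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(mesh.faces),
                           process=False)


FISSURE_NAMES = ("left_oblique", "right_oblique", "right_horizontal")


def write_reports_csv(path, case_id, reports):
    new = not __import__("os").path.exists(str(path))
    with open(path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(["case", "fissure", "assd_mm", "sdsd_mm",
                             "hd_mm", "na"])
        for name, r in zip(FISSURE_NAMES, reports):
            writer.writerow([case_id, name, r.assd, r.sdsd, r.hd, r.na])


def write_summary_json(path, aggregate, na_count):
    with open(path, "w") as fh:
        json.dump({"aggregate": aggregate, "na_total": na_count}, fh, indent=2)
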