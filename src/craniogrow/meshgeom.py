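"""Mesh primitives: volumes, plane circumferences, per-face area change.

Meshes are ``trimesh.Trimesh`` objects throughout the package (vertices in
mm).  Patch labels, where present, ride along as an integer-per-face array
in ``mesh.metadata["patch_labels"]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "NotWatertightError",
    "closed_mesh_volume",
    "plane_circumference",
    "AreaChangeMap",
    "area_change_map",
    "face_areas",
    "closest_on_mesh",
    "points_inside",
    "write_face_scalar_ply",
    "surface_frames",
    "make_mesh",
]


class NotWatertightError(ValueError):
    pass


def make_mesh(vertices: np.ndarray, faces: np.ndarray,
              patch_labels: np.ndarray | None = None) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic processing/merging."""
    m = trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                        faces=np.asarray(faces, dtype=np.int64),
                        process=False)
    if patch_labels is not None:
        labels = np.asarray(patch_labels)
        if len(labels) != len(m.faces):
            raise ValueError("patch_labels must have one entry per face")
        m.metadata["patch_labels"] = labels
    return m


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Triangle areas from the cross-product formula."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces)
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def closed_mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume of a watertight mesh via the divergence theorem.

    Sums signed tetrahedron volumes det[v0, v1, v2]/6 over faces and returns
    the absolute value, so a consistently inward-oriented shell gives the
    same answer as an outward one (with a warning).

    Raises
    ------
    NotWatertightError
        If the mesh has boundary edges; the message reports how many.
    """
    if not mesh.is_watertight:
        n_open = int((trimesh.grouping.group_rows(
            mesh.edges_sorted, require_count=1)).shape[0])
        raise NotWatertightError(
            f"mesh is not watertight: {n_open} boundary (unshared) edges")
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    signed = np.einsum("ij,ij->i", v[f[:, 0]],
                       np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    if signed < 0:
        warnings.warn("mesh is inward-oriented; returning |signed volume|",
                      stacklevel=2)
    return float(abs(signed))


def plane_circumference(mesh: trimesh.Trimesh, p1: np.ndarray, p2: np.ndarray,
                        midsagittal_normal: np.ndarray) -> float:
    """Perimeter of the longest closed section of ``mesh`` by a plane.

    The cutting plane passes through ``p1`` and ``p2`` and is perpendicular
    to the midsagittal plane (given by its normal); this is the convention
    for the cranial-circumference measurement, taken through Glabella and
    Opisthocranion.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n_mid = np.asarray(midsagittal_normal, dtype=float)
    chord = p2 - p1
    normal = np.cross(chord, n_mid)
    nn = np.linalg.norm(normal)
    if nn < 1e-12 * max(np.linalg.norm(chord), 1.0):
        raise ValueError(
            "ambiguous plane: p1-p2 chord is parallel to the midsagittal normal")
    normal = normal / nn
    section = mesh.section(plane_origin=p1, plane_normal=normal)
    if section is None:
        raise ValueError("plane does not intersect the mesh")
    best = 0.0
    for poly in section.discrete:
        closed = np.allclose(poly[0], poly[-1])
        if not closed:
            continue
        best = max(best, float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()))
    if best == 0.0:
        raise ValueError("plane intersection yields no closed polyline")
    return best


@dataclass(frozen=True)
class AreaChangeMap:
    """Per-face percent area change between topology-identical meshes."""

    percent: np.ndarray  # one value per face

    @property
    def range(self) -> tuple[float, float]:
        return float(self.percent.min()), float(self.percent.max())

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"face_index": np.arange(len(self.percent)),
                             "percent": self.percent})


def area_change_map(reference: trimesh.Trimesh,
                    target: trimesh.Trimesh) -> AreaChangeMap:
    """Percent change in area of each corresponding triangle.

    Correspondence is by face index (both meshes must derive from a common
    template); percent = (area_target - area_reference)/area_reference * 100,
    so positive values mark regions that expand from reference to target.
    """
    if reference.faces.shape != target.faces.shape or \
            not np.array_equal(reference.faces, target.faces):
        raise ValueError("meshes do not share face topology")
    a_ref = face_areas(reference.vertices, reference.faces)
    a_tgt = face_areas(target.vertices, target.faces)
    if np.any(a_ref <= 0):
        raise ValueError("reference mesh has degenerate faces")
    return AreaChangeMap(percent=(a_tgt - a_ref) / a_ref * 100.0)


def closest_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                    n_candidates: int = 24):
    """Closest surface point, distance and face index for each query point.

    Candidate faces are prefiltered with a KD-tree on triangle centroids,
    then resolved exactly with point-to-triangle projections.  For smooth,
    reasonably uniform meshes (everything this package generates) two dozen
    candidates are ample.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles.view(np.ndarray)
    centroids = tris.mean(axis=1)
    k = min(n_candidates, len(tris))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    n, kk = cand.shape
    flat_tris = tris[cand.reshape(-1)]
    flat_pts = np.repeat(points, kk, axis=0)
    flat_closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
    d2 = ((flat_closest - flat_pts) ** 2).sum(axis=1).reshape(n, kk)
    best = d2.argmin(axis=1)
    rows = np.arange(n)
    closest = flat_closest.reshape(n, kk, 3)[rows, best]
    tri_id = cand[rows, best]
    return closest, np.sqrt(d2[rows, best]), tri_id


def points_inside(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Generalized winding-number containment test (watertight meshes).

    Sums signed solid angles (van Oosterom-Strackee) of all faces about
    each query point; winding number ~1 inside, ~0 outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles.view(np.ndarray)
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        a = tris[:, 0] - p
        b = tris[:, 1] - p
        c = tris[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", a, c) * lb)
        winding = np.arctan2(num, den).sum() / (2.0 * np.pi)
        out[i] = abs(winding) > 0.5
    return out


def write_face_scalar_ply(mesh: trimesh.Trimesh, values: np.ndarray,
                          path) -> None:
    """ASCII PLY with a per-face float ``quality`` property (e.g. the
    percent area change of an AreaChangeMap)."""
    values = np.asarray(values, float)
    if len(values) != len(mesh.faces):
        raise ValueError("need one scalar per face")
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property float quality\nend_header\n")
        for row in v:
            fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
        for tri, q in zip(f, values):
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]} {q:.9g}\n")


def surface_frames(mesh: trimesh.Trimesh, points: np.ndarray):
    """Project points to the surface; return positions, normals, tangents.

    Normals are barycentric interpolations of area-weighted vertex normals
    at the closest surface point; tangent bases are orthonormal 3x2 frames
    spanning the plane perpendicular to each normal.

    Returns
    -------
    (projected (n,3), normals (n,3), tangents (n,3,2))
    """
    points = np.asarray(points, dtype=float)
    closest, _dist, tri_id = closest_on_mesh(mesh, points)
    tri_vertices = mesh.faces[tri_id]
    bary = trimesh.triangles.points_to_barycentric(
        mesh.triangles[tri_id], closest)
    vn = mesh.vertex_normals.view(np.ndarray)
    normals = np.einsum("ij,ijk->ik", bary, vn[tri_vertices])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    # fall back to the face normal where interpolation degenerates
    bad = norms[:, 0] < 1e-12
    if np.any(bad):
        normals[bad] = mesh.face_normals[tri_id[bad]]
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / norms
    # tangent basis: pick the coordinate axis least aligned with the normal
    ref = np.zeros_like(normals)
    ref[np.arange(len(normals)), np.argmin(np.abs(normals), axis=1)] = 1.0
    t1 = np.cross(normals, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    tangents = np.stack([t1, t2], axis=2)
    return closest, normals, tangents
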