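"""Group surface models for 3-D spatially resolved transcriptomics.

A tissue/organ group in a 3-D embedding is summarized by the convex hull
of its points, returned as a closed, consistently outward-oriented
triangle mesh.  Alpha-shapes can be plugged in through the ``builder``
hook; the convex hull is the default and the only built-in.
Meshes export to OFF and to a minimal glTF-style JSON (positions +
triangle indices), both plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .dataset import CellDataset


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (v, 3)
    faces: np.ndarray  # (f, 3) int, outward-oriented

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_face_counts(self) -> dict:
        counts = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                e = (min(a, b), max(a, b))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def is_closed(self) -> bool:
        """Closed + orientable: every edge shared by exactly two faces."""
        return all(c == 2 for c in self.edge_face_counts().values())

    def volume(self) -> float:
        """Signed-tetrahedron volume from the face decomposition."""
        v = self.vertices
        total = 0.0
        for a, b, c in self.faces:
            total += np.dot(v[a], np.cross(v[b], v[c])) / 6.0
        return abs(total)


def convex_hull_mesh(points: np.ndarray) -> TriangleMesh:
    """Convex hull of >= 4 non-coplanar 3-D points, outward-oriented."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(pts) < 4:
        raise ValueError(f"need >= 4 points for a 3-D hull, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate geometry (coplanar/collinear points): {e}") from e

    used = np.unique(hull.simplices)
    remap = {old: new for new, old in enumerate(used)}
    vertices = pts[used]
    centroid = vertices.mean(axis=0)
    faces = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        tri = [remap[i] for i in simplex]
        a, b, c = (vertices[i] for i in tri)
        normal = np.cross(b - a, c - a)
        # flip so the triangle normal agrees with qhull's outward facet normal
        if np.dot(normal, eq[:3]) < 0:
            tri = [tri[0], tri[2], tri[1]]
        faces.append(tri)
    return TriangleMesh(vertices, np.array(faces, dtype=int))


def build_surface(
    ds: CellDataset,
    embedding_3d: str,
    group_column: str,
    group_label: str,
    builder: Optional[Callable[[np.ndarray], TriangleMesh]] = None,
) -> TriangleMesh:
    """Surface model of one group of cells in a 3-D embedding."""
    if embedding_3d not in ds.embeddings:
        raise KeyError(f"unknown embedding {embedding_3d!r}")
    emb = ds.embeddings[embedding_3d]
    if emb.shape[1] != 3:
        raise ValueError(f"embedding {embedding_3d!r} is {emb.shape[1]}-D, need 3-D")
    labels = ds.metadata[group_column].astype(str).to_numpy()
    rows = np.where(labels == str(group_label))[0]
    if len(rows) < 4:
        raise ValueError(f"group {group_label!r} has {len(rows)} cells; need >= 4")
    return (builder or convex_hull_mesh)(emb[rows])


def contains_points(mesh: TriangleMesh, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True where a point lies inside or on the (convex) mesh."""
    hull = ConvexHull(mesh.vertices)
    pts = np.asarray(points, dtype=float)
    eq = hull.equations  # outward: eq[:3] . x + eq[3] <= 0 inside
    d = pts @ eq[:, :3].T + eq[:, 3]
    return np.all(d <= tol, axis=1)


def write_off(mesh: TriangleMesh, path: str):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_off(path: str) -> TriangleMesh:
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    if lines[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in l.split()] for l in lines[2 : 2 + nv]])
    faces = np.array(
        [[int(x) for x in l.split()[1:4]] for l in lines[2 + nv : 2 + nv + nf]], dtype=int
    )
    return TriangleMesh(verts, faces)


def write_gltf_json(mesh: TriangleMesh, path: str, name: str = "surface"):
    """Minimal glTF-flavoured JSON: positions + triangle indices, no binary."""
    doc = {
        "asset": {"version": "2.0", "generator": "omicview"},
        "meshes": [
            {
                "name": name,
                "primitives": [
                    {
                        "mode": 4,  # TRIANGLES
                        "attributes": {"POSITION": mesh.vertices.tolist()},
                        "indices": mesh.faces.ravel().tolist(),
                    }
                ],
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
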