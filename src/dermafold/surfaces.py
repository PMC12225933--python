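"""Triangular surface container shared by segmentation and pattern analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TriSurface:
    """A triangulated surface with optional per-vertex scalar fields.

    ``vertices`` are 3D coordinates, ``faces`` index triples wound so face
    normals point outward (away from the tissue).  Per-vertex scalars such
    as thickness or curvature live in ``vertex_data`` under named keys.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_data: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_areas(self):
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        a2 = np.linalg.norm(cr, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(a2[:, None] > 0, cr / a2[:, None], 0.0)
        return n, a2 / 2.0

    def area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit where defined)."""
        fn, fa = self.face_normals_areas()
        vn = np.zeros_like(self.vertices)
        for c in range(3):
            np.add.at(vn, self.faces[:, c], fn * fa[:, None])
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return np.where(norm > 0, vn / norm, 0.0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of incident face areas)."""
        _, fa = self.face_normals_areas()
        va = np.zeros(self.n_vertices)
        for c in range(3):
            np.add.at(va, self.faces[:, c], fa / 3.0)
        return va

    def edges_unique(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_face_counts(self):
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def nonmanifold_edges(self) -> np.ndarray:
        uniq, counts = self.edge_face_counts()
        return uniq[counts > 2]

    def is_manifold(self) -> bool:
        return len(self.nonmanifold_edges()) == 0

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on edges used by exactly one face."""
        uniq, counts = self.edge_face_counts()
        return np.unique(uniq[counts == 1])

    def drop_degenerate_faces(self, min_area: float = 1e-12) -> "TriSurface":
        _, fa = self.face_normals_areas()
        return TriSurface(
            self.vertices, self.faces[fa > min_area],
            dict(self.vertex_data), dict(self.metadata),
        )

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )
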