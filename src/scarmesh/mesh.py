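"""Indexed triangle meshes with optional per-vertex color and layer material."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh


@dataclass
class Material:
    """Layer appearance: base color, opacity and a name for export."""

    color: tuple[float, float, float] = (0.8, 0.8, 0.8)  # RGB in [0, 1]
    alpha: float = 1.0
    name: str = "material"

    def __post_init__(self) -> None:
        self.color = tuple(float(c) for c in self.color)  # type: ignore[assignment]
        self.alpha = float(self.alpha)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def rgba_uint8(self) -> np.ndarray:
        return np.round(np.array([*self.color, self.alpha]) * 255).astype(np.uint8)


@dataclass
class TriMesh:
    """Triangle mesh: vertices in mm, faces as (F, 3) vertex-index triples.

    ``vertex_colors`` is an optional (V, 4) RGBA array (uint8 or float in
    [0, 1]); ``material`` is an optional per-layer color + alpha used when
    the mesh is exported as a scene layer.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None
    material: Material | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.vertex_colors is not None:
            vc = np.asarray(self.vertex_colors)
            if vc.dtype != np.uint8:
                vc = np.round(np.clip(vc, 0, 1) * 255).astype(np.uint8)
            if vc.shape != (len(self.vertices), 4):
                raise ValueError("vertex_colors must be (V, 4) RGBA")
            self.vertex_colors = vc

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_sorted(self) -> np.ndarray:
        """All face edges as sorted vertex-index pairs, (3F, 2)."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def is_watertight(self) -> bool:
        """True if every edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        _, counts = np.unique(self.edges_sorted(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_closed(self) -> bool:
        """True if every edge bounds an even, positive number of faces.

        Weaker than :meth:`is_watertight`: voxel boundary shells with
        diagonally edge-touching cubes have 4-face edges yet still
        enclose their volume exactly.
        """
        if self.n_faces == 0:
            return False
        _, counts = np.unique(self.edges_sorted(), axis=0, return_counts=True)
        return bool(np.all(counts % 2 == 0))

    def euler_characteristic(self) -> int:
        """V - E + F with E the number of distinct undirected edges."""
        n_edges = len(np.unique(self.edges_sorted(), axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def signed_volume(self) -> float:
        """Enclosed volume in mm^3 via the divergence theorem.

        Positive for outward-oriented watertight meshes; only meaningful
        when the mesh is closed.
        """
        v = self.vertices - self.vertices.mean(axis=0)  # reduce roundoff
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    # -- interop ----------------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        tm = _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )
        if self.vertex_colors is not None:
            tm.visual = _trimesh.visual.ColorVisuals(
                tm, vertex_colors=self.vertex_colors.copy()
            )
        return tm

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        colors = None
        if isinstance(tm.visual, _trimesh.visual.ColorVisuals) and (
            tm.visual.kind == "vertex"
        ):
            colors = np.asarray(tm.visual.vertex_colors, dtype=np.uint8)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), vertex_colors=colors)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_colors is None else self.vertex_colors.copy(),
            self.material,
        )


def connected_components(mesh: TriMesh) -> list[np.ndarray]:
    """Face index arrays of the mesh's vertex-connected components."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as _cc

    if mesh.n_faces == 0:
        return []
    e = mesh.edges_sorted()
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    n, labels = _cc(adj, directed=False)
    face_label = labels[mesh.faces[:, 0]]
    return [np.flatnonzero(face_label == i) for i in range(n) if np.any(face_label == i)]
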