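"""Surface meshes, ellipsoid specifications and cell tessellations.

The seed coat outer surface is represented as a triangulated surface in
micrometre coordinates.  Epidermal cells are represented as a labelling of
mesh faces (a :class:`CellTessellation`), mirroring how cell-segmented
2.5D meshes are produced from confocal stacks in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

__all__ = [
    "EllipsoidSpec",
    "SurfaceMesh",
    "CellTessellation",
    "InvalidSpecError",
    "TopologyError",
]


class InvalidSpecError(ValueError):
    """Raised for geometrically invalid generator specifications."""


class TopologyError(ValueError):
    """Raised when a mesh violates a required topological property."""


@dataclass(frozen=True)
class EllipsoidSpec:
    """Triaxial ellipsoid semi-axes in µm.

    ``a`` is the semi-length (long axis, x), ``b`` the semi-width (y) and
    ``c`` the semi-thickness (z); a flattened seed has ``a >= b >= c``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidSpecError(f"semi-axes must be positive, got {(self.a, self.b, self.c)}")
        if not (self.a >= self.b >= self.c):
            raise InvalidSpecError(f"require a >= b >= c, got {(self.a, self.b, self.c)}")

    @classmethod
    def two_dpa_seed(cls) -> "EllipsoidSpec":
        """Default flattened seed at 2 days post anthesis.

        Length:width aspect ratio 1.7 and thickness 15% below width; the
        absolute 100 µm width scale is a convention (direction and
        anisotropy outputs are scale-free).
        """
        return cls(170.0, 100.0, 85.0)

    @classmethod
    def sphere(cls, radius: float) -> "EllipsoidSpec":
        return cls(radius, radius, radius)

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """(x/a)² + (y/b)² + (z/c)² for each point (1 on the surface)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.einsum("ij,ij->i", p / self.semi_axes, p / self.semi_axes)


class SurfaceMesh:
    """Triangulated surface with outward face normals (µm coordinates)."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        self._trimesh: Optional[trimesh.Trimesh] = None

    # -- cached geometric quantities -------------------------------------
    @property
    def as_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh.face_normals)

    @property
    def face_areas(self) -> np.ndarray:
        return np.asarray(self.as_trimesh.area_faces)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def centroid(self) -> np.ndarray:
        aw = self.face_areas[:, None]
        return (self.face_centroids * aw).sum(axis=0) / aw.sum()

    @property
    def mean_edge_length(self) -> float:
        return float(self.as_trimesh.edges_unique_length.mean())

    @property
    def is_closed(self) -> bool:
        """Every edge shared by exactly two faces."""
        return bool(self.as_trimesh.is_watertight)

    def require_closed(self) -> None:
        if not self.is_closed:
            raise TopologyError("mesh is not a closed 2-manifold")

    def check_outward_normals(self) -> bool:
        """Normals point away from the centroid (valid for star-shaped surfaces)."""
        r = self.face_centroids - self.centroid
        return bool((np.einsum("ij,ij->i", r, self.face_normals) > 0).all())

    def face_adjacency(self):
        """Sparse symmetric face-adjacency matrix (shared-edge neighbours)."""
        from scipy import sparse

        adj = self.as_trimesh.face_adjacency
        m = self.n_faces
        data = np.ones(len(adj), dtype=np.int8)
        mat = sparse.coo_matrix((data, (adj[:, 0], adj[:, 1])), shape=(m, m))
        return (mat + mat.T).tocsr()

    def vertex_graph(self):
        """Sparse vertex graph weighted by edge length, for geodesic distances."""
        from scipy import sparse

        edges = self.as_trimesh.edges_unique
        w = self.as_trimesh.edges_unique_length
        n = self.n_vertices
        mat = sparse.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
        return (mat + mat.T).tocsr()

    def save(self, path: str) -> None:
        """Write as OBJ or PLY (ascii), by file extension."""
        ext = str(path).rsplit(".", 1)[-1].lower()
        if ext == "ply":
            data = trimesh.exchange.ply.export_ply(self.as_trimesh, encoding="ascii")
            with open(path, "wb") as fh:
                fh.write(data)
        else:
            self.as_trimesh.export(path)

    @classmethod
    def load(cls, path: str) -> "SurfaceMesh":
        tm = trimesh.load_mesh(path, process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class CellTessellation:
    """Assignment of each mesh face to one cell.

    ``face_cell[i]`` is the cell id of face ``i``.  Cell ids are contiguous
    integers starting at 0 unless the tessellation was produced by division,
    in which case offspring receive fresh ids.  ``lineage`` optionally maps a
    parent cell id (in an earlier tessellation) to its offspring ids here.
    """

    mesh: SurfaceMesh
    face_cell: np.ndarray
    lineage: Optional[dict[int, frozenset[int]]] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.face_cell = np.asarray(self.face_cell, dtype=np.int64)
        if len(self.face_cell) != self.mesh.n_faces:
            raise ValueError("face_cell must label every face exactly once")

    @property
    def cell_ids(self) -> np.ndarray:
        if "ids" not in self._cache:
            self._cache["ids"] = np.unique(self.face_cell)
        return self._cache["ids"]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_faces(self, cell_id: int) -> np.ndarray:
        return np.flatnonzero(self.face_cell == cell_id)

    @property
    def cell_areas(self) -> np.ndarray:
        """Per-cell surface area (µm²), ordered as ``cell_ids``."""
        if "areas" not in self._cache:
            fa = self.mesh.face_areas
            idx = np.searchsorted(self.cell_ids, self.face_cell)
            self._cache["areas"] = np.bincount(idx, weights=fa, minlength=self.n_cells)
        return self._cache["areas"]

    @property
    def cell_centroids(self) -> np.ndarray:
        """Area-weighted 3D centroid per cell (µm), ordered as ``cell_ids``."""
        if "centroids" not in self._cache:
            fc = self.mesh.face_centroids
            fa = self.mesh.face_areas
            idx = np.searchsorted(self.cell_ids, self.face_cell)
            out = np.zeros((self.n_cells, 3))
            for k in range(3):
                out[:, k] = np.bincount(idx, weights=fc[:, k] * fa, minlength=self.n_cells)
            out /= self.cell_areas[:, None]
            self._cache["centroids"] = out
        return self._cache["centroids"]

    @property
    def cell_normals(self) -> np.ndarray:
        """Area-weighted mean outward unit normal per cell."""
        if "normals" not in self._cache:
            fn = self.mesh.face_normals
            fa = self.mesh.face_areas
            idx = np.searchsorted(self.cell_ids, self.face_cell)
            out = np.zeros((self.n_cells, 3))
            for k in range(3):
                out[:, k] = np.bincount(idx, weights=fn[:, k] * fa, minlength=self.n_cells)
            out /= np.linalg.norm(out, axis=1, keepdims=True)
            self._cache["normals"] = out
        return self._cache["normals"]

    def is_cell_connected(self, cell_id: int) -> bool:
        from scipy.sparse.csgraph import connected_components

        faces = self.cell_faces(cell_id)
        if len(faces) <= 1:
            return True
        sub = self.mesh.face_adjacency()[np.ix_(faces, faces)]
        n, _ = connected_components(sub, directed=False)
        return n == 1

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"face_id": np.arange(self.mesh.n_faces), "cell_id": self.face_cell})

    def save(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, mesh: SurfaceMesh, path: str) -> "CellTessellation":
        import pandas as pd

        df = pd.read_csv(path).sort_values("face_id")
        return cls(mesh, df["cell_id"].to_numpy())
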