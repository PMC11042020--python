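"""Tetrahedral mesh container for the cylindrical EIT domain.

Coordinates are stored in metres. Electrode patches are sets of boundary
faces (triangles on the lateral surface); they are exact unions of faces
because the structured mesher places node lines on electrode edges.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


class MeshValidationError(ValueError):
    pass


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive under the stored orientation)."""
    a = nodes[tets[:, 0]]
    b = nodes[tets[:, 1]] - a
    c = nodes[tets[:, 2]] - a
    d = nodes[tets[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(b, c), d) / 6.0


@dataclass
class Mesh:
    nodes: np.ndarray  # (n_nodes, 3), metres
    tets: np.ndarray  # (N, 4) int
    boundary_faces: np.ndarray = field(default=None)  # (B, 3) int
    electrode_faces: dict = field(default_factory=dict)  # electrode (1..48) -> face indices

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.boundary_faces is None:
            self.boundary_faces = _extract_boundary_faces(self.tets)
        self.boundary_faces = np.asarray(self.boundary_faces, dtype=np.int64)
        self._centroids = None
        self._volumes = None
        self._hash = None

    # -- derived, cached ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    @property
    def element_centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.tets].mean(axis=1)
        return self._centroids

    @property
    def element_volumes(self) -> np.ndarray:
        if self._volumes is None:
            self._volumes = tet_volumes(self.nodes, self.tets)
        return self._volumes

    @property
    def mesh_hash(self) -> str:
        if self._hash is None:
            h = hashlib.sha256()
            h.update(np.round(self.nodes, 12).tobytes())
            h.update(self.tets.tobytes())
            for k in sorted(self.electrode_faces):
                h.update(np.asarray(sorted(self.electrode_faces[k]), dtype=np.int64).tobytes())
            self._hash = h.hexdigest()[:16]
        return self._hash

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_faces)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_elements < 4:
            raise MeshValidationError("mesh must contain at least 4 tetrahedra")
        vols = self.element_volumes
        if np.any(vols <= 0):
            raise MeshValidationError("non-positive tetrahedron volume")
        counts = _face_share_counts(self.tets)
        if np.any((counts != 1) & (counts != 2)):
            raise MeshValidationError("a face is shared by more than two tetrahedra")
        # boundary faces must tile a closed surface: every boundary edge twice
        edges = np.vstack(
            [self.boundary_faces[:, [0, 1]], self.boundary_faces[:, [1, 2]], self.boundary_faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, ecnt = np.unique(edges, axis=0, return_counts=True)
        if np.any(ecnt != 2):
            raise MeshValidationError("boundary faces do not form a closed surface")
        # electrode patches disjoint
        seen: set[int] = set()
        for el, faces in self.electrode_faces.items():
            fs = set(int(f) for f in faces)
            if not fs:
                raise MeshValidationError(f"electrode {el} has an empty patch")
            if seen & fs:
                raise MeshValidationError("electrode patches are not pairwise disjoint")
            seen |= fs


def _face_share_counts(tets: np.ndarray) -> np.ndarray:
    faces = np.vstack(
        [tets[:, [1, 2, 3]], tets[:, [0, 2, 3]], tets[:, [0, 1, 3]], tets[:, [0, 1, 2]]]
    )
    faces = np.sort(faces, axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    return counts


def _extract_boundary_faces(tets: np.ndarray) -> np.ndarray:
    faces = np.vstack(
        [tets[:, [1, 2, 3]], tets[:, [0, 2, 3]], tets[:, [0, 1, 3]], tets[:, [0, 1, 2]]]
    )
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return uniq[counts == 1]


def face_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = nodes[faces[:, 0]]
    b = nodes[faces[:, 1]] - a
    c = nodes[faces[:, 2]] - a
    return 0.5 * np.linalg.norm(np.cross(b, c), axis=1)
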