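"""Complete-electrode-model finite element forward solver.

First-order tetrahedral elements. The unknowns are the nodal potentials, the
48 electrode potentials, and one Lagrange multiplier enforcing the zero-mean
grounding convention on the electrode potentials.

Contact layer model
-------------------
The electrode contact is modelled as a thin resistive layer *of the measured
medium itself*: the surface conductance density of electrode ``l`` over a
boundary face is ``sigma_face / zeta_l`` where ``sigma_face`` is the
conductivity of the element owning the face and ``zeta_l`` (ohm * m) is a
geometric layer constant. ``CEMParams.contact_impedance`` states the
effective contact impedance (ohm * m^2) at the reference background
conductivity, so ``zeta_l = contact_impedance * sigma_ref``. The consequence
is that the whole stiffness operator is exactly homogeneous of degree one in
the conductivity vector, A(sigma) = sum_n sigma_n K_n, which yields the
exact measurement scaling law v(c * sigma) = v(sigma) / c and the Euler
identity J sigma = -v used to validate the sensitivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import Mesh, face_areas
from .protocol import ExcitationPattern, N_ELECTRODES

US_PER_CM = 1e-4  # 1 uS/cm = 1e-4 S/m
SIGMA_REF_S_PER_M = 350 * US_PER_CM  # reference background, 350 uS/cm


class BindingError(ValueError):
    """A field/matrix is used with a mesh or protocol it was not built for."""


@dataclass
class ConductivityField:
    """Per-element conductivity in S/m, bound to a mesh by hash."""

    values: np.ndarray
    mesh_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("conductivity values must be a vector")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("conductivity values must be positive and finite")

    @classmethod
    def homogeneous(cls, mesh: Mesh, sigma_S_per_m: float) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, float(sigma_S_per_m)), mesh.mesh_hash)

    @classmethod
    def from_uS_per_cm(cls, mesh: Mesh, values_uS_per_cm) -> "ConductivityField":
        vals = np.asarray(values_uS_per_cm, dtype=float) * US_PER_CM
        if vals.ndim == 0:
            vals = np.full(mesh.n_elements, float(vals))
        return cls(vals, mesh.mesh_hash)

    def to_uS_per_cm(self) -> np.ndarray:
        return self.values / US_PER_CM

    def check_bound(self, mesh: Mesh) -> None:
        if self.mesh_hash != mesh.mesh_hash:
            raise BindingError("conductivity field is bound to a different mesh")
        if self.values.size != mesh.n_elements:
            raise BindingError("conductivity length does not match mesh element count")


@dataclass(frozen=True)
class CEMParams:
    """Electrode model parameters.

    contact_impedance: effective per-electrode contact impedance (ohm*m^2)
        at the reference background conductivity (350 uS/cm).
    current_amplitude: drive current (A).
    """

    contact_impedance: float = 1e-4
    current_amplitude: float = 1e-3
    sigma_ref: float = SIGMA_REF_S_PER_M

    def __post_init__(self) -> None:
        if self.contact_impedance <= 0:
            raise ValueError("contact impedance must be positive")
        if self.current_amplitude <= 0:
            raise ValueError("current amplitude must be positive")

    @property
    def zeta(self) -> float:
        """Geometric contact layer constant (ohm * m)."""
        return self.contact_impedance * self.sigma_ref


@dataclass
class PotentialSet:
    """Forward solutions: one nodal + electrode potential vector per excitation."""

    nodal_potentials: np.ndarray  # (n_exc, n_nodes)
    electrode_potentials: np.ndarray  # (n_exc, 48)
    mesh_hash: str = ""

    @property
    def n_excitations(self) -> int:
        return self.electrode_potentials.shape[0]


_FACE_MASS = (np.ones((3, 3)) + np.eye(3)) / 12.0


class FEMContext:
    """Precomputed sigma-independent element data for one mesh + CEM config.

    Caches P1 gradient operators, element stiffness kernels, the boundary
    face -> owning element map, and sparse assembly index patterns so that
    repeated assemblies (phantom sweeps, Gauss-Newton iterations) only
    rescale data vectors.
    """

    def __init__(self, mesh: Mesh, cem: CEMParams):
        self.mesh = mesh
        self.cem = cem
        nodes, tets = mesh.nodes, mesh.tets
        N = mesh.n_elements
        x0 = nodes[tets[:, 0]]
        M = np.stack([nodes[tets[:, k]] - x0 for k in (1, 2, 3)], axis=1)  # (N,3,3)
        # barycentric gradients: grad(lambda_i) = row i-1 of inv(M^T), i=1..3
        G123 = np.linalg.inv(np.transpose(M, (0, 2, 1)))
        # G123[n, i, :] = grad of basis i+1; grad of basis 0 = -sum
        G0 = -G123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([G0, G123], axis=1)  # (N, 4, 3)
        self.volumes = np.abs(mesh.element_volumes)
        # element conduction kernels vol * G G^T, (N,4,4)
        self.k_vol = self.volumes[:, None, None] * np.einsum("nik,njk->nij", self.grads, self.grads)

        # boundary face ownership
        self._build_face_owners()
        self._build_pattern()

    # ------------------------------------------------------------------
    def _build_face_owners(self) -> None:
        mesh = self.mesh
        face_key = {tuple(sorted(f)): i for i, f in enumerate(mesh.boundary_faces)}
        owner = np.full(len(mesh.boundary_faces), -1, dtype=np.int64)
        for n, tet in enumerate(mesh.tets):
            for drop in range(4):
                tri = tuple(sorted(np.delete(tet, drop)))
                i = face_key.get(tri)
                if i is not None:
                    owner[i] = n
        self.face_owner = owner
        self.areas = face_areas(mesh.nodes, mesh.boundary_faces)
        # electrode face table: list of (electrode0, face_idx, owner_elem, 3 nodes, area)
        rows = []
        for el, faces in self.mesh.electrode_faces.items():
            for f in faces:
                rows.append((el - 1, int(f), int(owner[f])))
        self.contact_faces = rows

    def _build_pattern(self) -> None:
        mesh, cem = self.mesh, self.cem
        nn = mesh.n_nodes
        ne = N_ELECTRODES
        self.n_dof = nn + ne + 1
        rows, cols, scale_elem, base = [], [], [], []
        tets = mesh.tets
        # conduction block entries: entry (i,j) of element n scales with sigma_n
        ii = np.repeat(tets, 4, axis=1).ravel()
        jj = np.tile(tets, (1, 4)).ravel()
        rows.append(ii)
        cols.append(jj)
        scale_elem.append(np.repeat(np.arange(mesh.n_elements), 16))
        base.append(self.k_vol.reshape(-1))
        # contact terms, all scaled by sigma of the owning element / zeta
        inv_zeta = 1.0 / cem.zeta
        for el0, f, n_own in self.contact_faces:
            tri = mesh.boundary_faces[f]
            a = self.areas[f]
            m = a * _FACE_MASS * inv_zeta
            # u-u block
            rows.append(np.repeat(tri, 3))
            cols.append(np.tile(tri, 3))
            base.append(m.ravel())
            scale_elem.append(np.full(9, n_own))
            # u-U coupling
            w = -a / 3.0 * inv_zeta
            rows.append(np.concatenate([tri, np.full(3, nn + el0)]))
            cols.append(np.concatenate([np.full(3, nn + el0), tri]))
            base.append(np.full(6, w))
            scale_elem.append(np.full(6, n_own))
            # U-U diagonal
            rows.append(np.array([nn + el0]))
            cols.append(np.array([nn + el0]))
            base.append(np.array([a * inv_zeta]))
            scale_elem.append(np.array([n_own]))
        # grounding constraint sum(U) = 0 via Lagrange multiplier (sigma-free;
        # scaling it with mean sigma keeps the operator homogeneous, but the
        # multiplier block never mixes with the physics so a constant is fine)
        g = nn + ne
        rows.append(np.concatenate([np.arange(nn, nn + ne), np.full(ne, g)]))
        cols.append(np.concatenate([np.full(ne, g), np.arange(nn, nn + ne)]))
        base.append(np.ones(2 * ne))
        scale_elem.append(np.full(2 * ne, -1))  # -1: no sigma scaling

        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)
        self._base = np.concatenate(base)
        self._scale_elem = np.concatenate(scale_elem)

    # ------------------------------------------------------------------
    def assemble(self, sigma: ConductivityField) -> sp.csc_matrix:
        """CEM stiffness system (symmetric); grounded by the multiplier row."""
        sigma.check_bound(self.mesh)
        s = np.where(self._scale_elem >= 0, sigma.values[np.maximum(self._scale_elem, 0)], 1.0)
        A = sp.coo_matrix(
            (self._base * s, (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
        )
        return A.tocsc()

    def conduction_matrix(self, sigma: ConductivityField) -> sp.csr_matrix:
        """Interior conduction block only (nodal x nodal), for diagnostics."""
        sigma.check_bound(self.mesh)
        tets = self.mesh.tets
        ii = np.repeat(tets, 4, axis=1).ravel()
        jj = np.tile(tets, (1, 4)).ravel()
        data = (sigma.values[:, None, None] * self.k_vol).reshape(-1)
        nn = self.mesh.n_nodes
        return sp.coo_matrix((data, (ii, jj)), shape=(nn, nn)).tocsr()

    def drive_rhs(self, pattern: ExcitationPattern) -> np.ndarray:
        nn = self.mesh.n_nodes
        B = np.zeros((self.n_dof, pattern.n_excitations))
        I = self.cem.current_amplitude
        for e, (in1, in2) in enumerate(pattern.drive_pairs):
            B[nn + in1 - 1, e] = I
            B[nn + in2 - 1, e] = -I
        return B

    def solve(self, sigma: ConductivityField, pattern: ExcitationPattern) -> PotentialSet:
        A = self.assemble(sigma)
        B = self.drive_rhs(pattern)
        try:
            lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular configs
            raise RuntimeError(f"forward system factorization failed: {exc}") from exc
        X = lu.solve(B)
        # one step of iterative refinement keeps the relative residual ~1e-14
        X += lu.solve(B - A @ X)
        res = np.linalg.norm(A @ X - B) / max(np.linalg.norm(B), 1e-300)
        if not np.isfinite(res) or res > 1e-10:
            raise RuntimeError(f"forward solve residual {res:.2e} exceeds 1e-10")
        nn = self.mesh.n_nodes
        return PotentialSet(
            nodal_potentials=np.ascontiguousarray(X[:nn].T),
            electrode_potentials=np.ascontiguousarray(X[nn : nn + N_ELECTRODES].T),
            mesh_hash=self.mesh.mesh_hash,
        )


def assemble_system(mesh: Mesh, sigma: ConductivityField, cem: CEMParams) -> FEMContext:
    """Build (or rebuild) the linear-system handle for a mesh/CEM pair."""
    sigma.check_bound(mesh)
    return FEMContext(mesh, cem)


def solve_forward(
    mesh: Mesh,
    sigma: ConductivityField,
    cem: CEMParams,
    excitations: ExcitationPattern,
    context: FEMContext | None = None,
) -> PotentialSet:
    """Solve the CEM forward problem for every drive pair in the pattern."""
    sigma.check_bound(mesh)
    ctx = context if context is not None else FEMContext(mesh, cem)
    return ctx.solve(sigma, excitations)
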