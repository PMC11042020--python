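"""Adjoint-field sensitivity (Jacobian) matrix for the adjacent protocol.

Because the stiffness operator is linear in the element conductivities,
``A(sigma) = sum_n sigma_n K_n``, the derivative of measurement ``l``
(drive pair d, measurement pair p) with respect to ``sigma_n`` is

    J[l, n] = (1/I) w_p^T K_n w_d

where ``w_d`` and ``w_p`` are the forward solutions driving the respective
adjacent pairs at the drive amplitude ``I``. With the adjacent protocol the
measurement pairs coincide with the drive-pair set, so a single factorization
and 48 solves produce the full 2,160 x N matrix. The sign convention gives
``delta_v = J delta_sigma`` and the exact Euler identity ``J sigma = -v``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import CEMParams, ConductivityField, FEMContext, PotentialSet
from .mesh import Mesh
from .protocol import (
    ExcitationPattern,
    MeasurementScheme,
    N_PER_RING,
    protocol_hash,
)


@dataclass
class SensitivityMatrix:
    entries: np.ndarray  # (L, N), V per (S/m)
    protocol_hash: str
    mesh_hash: str

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("sensitivity matrix contains non-finite entries")


def _adjacent_pair_index(out1: int, out2: int) -> int:
    """Excitation index whose drive pair equals ring-adjacent pair (out1, out2)."""
    ring, loc = divmod(out1 - 1, N_PER_RING)
    expected = ring * N_PER_RING + loc % N_PER_RING + 1, ring * N_PER_RING + (loc + 1) % N_PER_RING + 1
    if (out1, out2) != expected:
        raise ValueError(f"measurement pair ({out1}, {out2}) is not ring-adjacent")
    return ring * N_PER_RING + loc


def compute_jacobian(
    mesh: Mesh,
    sigma: ConductivityField,
    cem: CEMParams,
    protocol: tuple[ExcitationPattern, MeasurementScheme],
    context: FEMContext | None = None,
    potentials: PotentialSet | None = None,
) -> SensitivityMatrix:
    pattern, scheme = protocol
    sigma.check_bound(mesh)
    ctx = context if context is not None else FEMContext(mesh, cem)
    pots = potentials if potentials is not None else ctx.solve(sigma, pattern)

    # sanity: the drive set must cover all 48 ring-adjacent pairs in order
    for e, (in1, in2) in enumerate(pattern.drive_pairs):
        if _adjacent_pair_index(in2, in1) != e:
            raise ValueError("excitation pattern is not the canonical adjacent ordering")

    drive_idx: list[int] = []
    pair_idx: list[int] = []
    for e, meas in enumerate(scheme.pairs):
        for out1, out2 in meas:
            drive_idx.append(e)
            pair_idx.append(_adjacent_pair_index(out1, out2))
    d_idx = np.asarray(drive_idx)
    p_idx = np.asarray(pair_idx)

    U_nodal = pots.nodal_potentials  # (48, n_nodes)
    U_el = pots.electrode_potentials  # (48, 48)
    I = cem.current_amplitude

    # element-wise field gradients for every solution: (48, N, 3)
    g = np.einsum("snj,njk->snk", U_nodal[:, mesh.tets], ctx.grads)
    # volume kernel products P[a, b, n] = vol_n * grad_a . grad_b
    P = np.einsum("ank,bnk->abn", g, g) * ctx.volumes[None, None, :]

    J = P[p_idx, d_idx, :] / I  # (L, N) volume part

    # contact-layer surface terms (faces under electrodes, owner element sigma)
    inv_zeta = 1.0 / ctx.cem.zeta
    for el0, f, n_own in ctx.contact_faces:
        tri = mesh.boundary_faces[f]
        a = ctx.areas[f]
        dv = U_nodal[:, tri] - U_el[:, el0][:, None]  # (48, 3)
        s1 = dv.sum(axis=1)
        C = (a * inv_zeta / 12.0) * (np.outer(s1, s1) + dv @ dv.T)  # (48, 48)
        J[:, n_own] += C[p_idx, d_idx] / I

    return SensitivityMatrix(
        entries=J,
        protocol_hash=protocol_hash(pattern, scheme),
        mesh_hash=mesh.mesh_hash,
    )
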