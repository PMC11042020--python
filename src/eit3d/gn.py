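"""Regularized Gauss-Newton absolute reconstruction (classical comparator).

Minimises the Tikhonov functional

    Phi(sigma) = ||v_meas - v(sigma)||^2 + lam * ||R (sigma - sigma_init)||^2

starting from the best-fit homogeneous field (a scalar least-squares fit,
exact because measurements scale as 1/sigma for homogeneous fields). Each
iteration recomputes the Jacobian at the current linearization point, solves
the damped normal equations and backtracks (step halving) until the
objective decreases. The regularization weight is specified relative to the
mean diagonal of J^T J so its effect is mesh- and scale-independent.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .fem import CEMParams, ConductivityField, FEMContext
from .jacobian import compute_jacobian
from .mesh import Mesh
from .protocol import ExcitationPattern, MeasurementScheme, VoltageFrame, extract_frame


@dataclass(frozen=True)
class GNConfig:
    lam: float = 1e-3  # regularization weight, relative to mean diag of J^T J
    prior: str = "identity"  # "identity" | "laplacian"
    max_iters: int = 10
    step_halvings: int = 8
    sigma_floor: float = 1e-10  # S/m clip
    rtol_objective: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("regularization weight must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.prior not in ("identity", "laplacian"):
            raise ValueError("prior must be 'identity' or 'laplacian'")


@dataclass
class GNResult:
    field: ConductivityField
    objective_history: list = field(default_factory=list)
    sigma_init: float = 0.0
    ipst_s: float = 0.0
    n_iters: int = 0


def element_adjacency_laplacian(mesh: Mesh) -> sp.csr_matrix:
    """Graph Laplacian over tets sharing a face."""
    faces = {}
    rows, cols = [], []
    for n, tet in enumerate(mesh.tets):
        for drop in range(4):
            key = tuple(sorted(np.delete(tet, drop)))
            other = faces.pop(key, None)
            if other is None:
                faces[key] = n
            else:
                rows += [n, other]
                cols += [other, n]
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(mesh.n_elements,) * 2).tocsr()
    deg = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    return (deg - A).tocsr()


def _prior_matrix(mesh: Mesh, config: GNConfig):
    if config.prior == "identity":
        return sp.identity(mesh.n_elements, format="csr")
    return element_adjacency_laplacian(mesh)


def gn_objective(
    frame: VoltageFrame,
    sigma: ConductivityField,
    config: GNConfig,
    ctx: FEMContext,
    pattern: ExcitationPattern,
    scheme: MeasurementScheme,
    sigma_init: np.ndarray,
    lam_abs: float,
    R=None,
) -> float:
    """Data misfit plus scaled Tikhonov prior; nonnegative by construction."""
    v = extract_frame(ctx.solve(sigma, pattern), scheme).values
    r = frame.values - v
    if R is None:
        R = _prior_matrix(ctx.mesh, config)
    d = sigma.values - sigma_init
    return float(r @ r + lam_abs * (R @ d) @ (R @ d))


def gn_reconstruct(
    frame: VoltageFrame,
    mesh: Mesh,
    cem: CEMParams,
    protocol: tuple[ExcitationPattern, MeasurementScheme],
    config: GNConfig = GNConfig(),
    context: FEMContext | None = None,
) -> GNResult:
    pattern, scheme = protocol
    t0 = time.perf_counter()
    ctx = context if context is not None else FEMContext(mesh, cem)
    v_meas = frame.values
    if v_meas.size != scheme.frame_length:
        raise ValueError("frame length does not match the protocol")

    # homogeneous initialization: v(c * 1) = v(1)/c, scalar least squares
    unit = ConductivityField.homogeneous(mesh, 1.0)
    v1 = extract_frame(ctx.solve(unit, pattern), scheme).values
    denom = float(v1 @ v_meas)
    if denom <= 0:
        raise RuntimeError("cannot fit a positive homogeneous background to the frame")
    sigma0 = float(v1 @ v1) / denom
    sigma_init = np.full(mesh.n_elements, sigma0)
    sigma = sigma_init.copy()

    R = _prior_matrix(mesh, config)
    RtR = (R.T @ R).toarray()

    fld = ConductivityField(sigma, mesh.mesh_hash)
    pots = ctx.solve(fld, pattern)
    v = extract_frame(pots, scheme).values
    lam_abs = None
    history = []
    obj = None
    n_done = 0
    for it in range(config.max_iters):
        J = compute_jacobian(mesh, fld, cem, protocol, context=ctx, potentials=pots).entries
        JtJ = J.T @ J
        if lam_abs is None:
            lam_abs = config.lam * float(np.trace(JtJ)) / mesh.n_elements
            obj = float((v_meas - v) @ (v_meas - v)) + lam_abs * float(
                (R @ (sigma - sigma_init)) @ (R @ (sigma - sigma_init))
            )
            history.append(obj)
        r = v_meas - v
        rhs = J.T @ r - lam_abs * (RtR @ (sigma - sigma_init))
        H = JtJ + lam_abs * RtR
        try:
            delta = sla.solve(H, rhs, assume_a="pos")
        except sla.LinAlgError as exc:
            raise RuntimeError(f"normal equations not positive definite: {exc}") from exc

        step = 1.0
        accepted = False
        for _ in range(config.step_halvings + 1):
            cand = np.clip(sigma + step * delta, config.sigma_floor, None)
            cand_f = ConductivityField(cand, mesh.mesh_hash)
            try:
                cand_pots = ctx.solve(cand_f, pattern)
            except RuntimeError:
                step *= 0.5
                continue
            cand_v = extract_frame(cand_pots, scheme).values
            d = cand - sigma_init
            cand_obj = float((v_meas - cand_v) @ (v_meas - cand_v)) + lam_abs * float(
                (R @ d) @ (R @ d)
            )
            if np.isfinite(cand_obj) and cand_obj < obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        n_done = it + 1
        rel_drop = (obj - cand_obj) / max(obj, 1e-300)
        sigma, fld, pots, v = cand, cand_f, cand_pots, cand_v
        obj = cand_obj
        history.append(obj)
        if rel_drop < config.rtol_objective:
            break

    return GNResult(
        field=ConductivityField(sigma, mesh.mesh_hash),
        objective_history=history,
        sigma_init=sigma0,
        ipst_s=time.perf_counter() - t0,
        n_iters=n_done,
    )
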