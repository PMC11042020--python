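"""Reconstruction quality metrics: RMSE, Pearson CC, and global SSIM.

Fields are unstructured per-element vectors, so SSIM is computed with global
means/variances/covariance over all elements rather than sliding windows.
The stabilising constants follow the conventional choice
``c1 = (0.01 * L)**2``, ``c2 = (0.03 * L)**2`` with ``L`` the dynamic range
of the reference field (floored to keep the ratio defined for constant
references).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

_C_FLOOR = 1e-24


@dataclass(frozen=True)
class MetricConfig:
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03


def _pair(P, A) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float).ravel()
    A = np.asarray(A, dtype=float).ravel()
    if P.size != A.size:
        raise ValueError(f"length mismatch: {P.size} vs {A.size}")
    if P.size == 0:
        raise ValueError("metrics are undefined for empty vectors")
    return P, A


def rmse(P, A) -> float:
    """Root mean squared difference between predicted and reference vectors."""
    P, A = _pair(P, A)
    return float(np.sqrt(np.mean((P - A) ** 2)))


def cc(P, A) -> float:
    """Pearson correlation coefficient; undefined for constant inputs."""
    P, A = _pair(P, A)
    sp = P.std()
    sa = A.std()
    if sp == 0 or sa == 0:
        raise ValueError("correlation is undefined for a constant input vector")
    return float(((P - P.mean()) * (A - A.mean())).mean() / (sp * sa))


def ssim(P, A, config: MetricConfig = MetricConfig()) -> float:
    """Global-statistics structural similarity; 1 iff the fields are identical."""
    P, A = _pair(P, A)
    L = float(A.max() - A.min())
    c1 = max((config.ssim_k1 * L) ** 2, _C_FLOOR)
    c2 = max((config.ssim_k2 * L) ** 2, _C_FLOOR)
    mu_p, mu_a = P.mean(), A.mean()
    var_p, var_a = P.var(), A.var()
    cov = ((P - mu_p) * (A - mu_a)).mean()
    return float(
        (2 * mu_p * mu_a + c1) * (2 * cov + c2)
        / ((mu_p**2 + mu_a**2 + c1) * (var_p + var_a + c2))
    )


@dataclass
class ReconstructionReport:
    rmse: float
    cc: float
    ssim: float
    ipst_s: float | None = None  # wall-clock inverse-problem solving time

    def to_json(self) -> str:
        return json.dumps(
            {"rmse": self.rmse, "cc": self.cc, "ssim": self.ssim, "ipst_s": self.ipst_s}
        )


def evaluate_reconstruction(
    pred, truth, config: MetricConfig = MetricConfig(), ipst_s: float | None = None
) -> ReconstructionReport:
    """Bundle RMSE/CC/SSIM for a predicted vs true conductivity field.

    Accepts raw vectors or ConductivityField objects; fields must share the
    same mesh binding.
    """
    p = getattr(pred, "values", pred)
    a = getattr(truth, "values", truth)
    hp = getattr(pred, "mesh_hash", None)
    ha = getattr(truth, "mesh_hash", None)
    if hp is not None and ha is not None and hp != ha:
        raise ValueError("prediction and truth are bound to different meshes")
    return ReconstructionReport(
        rmse=rmse(p, a), cc=cc(p, a), ssim=ssim(p, a, config), ipst_s=ipst_s
    )
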