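"""Distribution-similarity statistics for boundary-voltage quality grading.

Four statistics compare a measured voltage sample set against an ideal
(simulated, noise-free) reference:

* ``mmd`` — square root of the unbiased maximum-mean-discrepancy estimator
  with a Gaussian kernel (bandwidth by the median pairwise-distance
  heuristic over the pooled samples, negative estimates clipped at zero);
* ``kde_ise`` — integrated squared difference between the two Gaussian
  kernel density estimates (Silverman's rule bandwidths, trapezoidal
  integration on a grid spanning both samples plus three bandwidths);
* ``lmmd`` — mean of per-window MMDs over contiguous equal windows of the
  ordered sequences (local distributional differences);
* ``knndc`` — for every point of X, the mean Euclidean distance to its k
  nearest neighbours in Y, averaged over X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

_BW_FLOOR = 1e-12


@dataclass(frozen=True)
class QualityConfig:
    n_windows: int = 10
    k_neighbors: int = 5
    n_grid: int = 512
    grid_pad_bandwidths: float = 3.0
    mmd_bandwidth: float | None = None  # None -> median heuristic
    kde_bandwidth: float | None = None  # None -> Silverman's rule

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _median_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    Z = np.vstack([X, Y])
    d = cdist(Z, Z)
    vals = d[np.triu_indices(len(Z), k=1)]
    med = float(np.median(vals))
    return max(med, _BW_FLOOR)


def _gauss_kernel(A: np.ndarray, B: np.ndarray, h: float) -> np.ndarray:
    d2 = cdist(A, B, "sqeuclidean")
    return np.exp(-d2 / (2.0 * h * h))


def mmd(X, Y, config: QualityConfig = QualityConfig()) -> float:
    """Unbiased Gaussian-kernel MMD (its square root, clipped at zero)."""
    X, Y = _as2d(X), _as2d(Y)
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("mmd requires at least two points in each sample set")
    h = config.mmd_bandwidth if config.mmd_bandwidth is not None else _median_bandwidth(X, Y)
    kxx = _gauss_kernel(X, X, h)
    kyy = _gauss_kernel(Y, Y, h)
    kxy = _gauss_kernel(X, Y, h)
    est = (
        (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
        + (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
        - 2.0 * kxy.mean()
    )
    return float(np.sqrt(max(est, 0.0)))


def _silverman(x: np.ndarray) -> float:
    n = x.size
    if n < 2:
        raise ValueError("Silverman's rule requires at least two points")
    std = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(std, iqr / 1.34) if iqr > 0 else std
    if spread <= 0:
        warnings.warn("degenerate (zero-variance) sample; bandwidth floored", stacklevel=3)
        return _BW_FLOOR
    return 0.9 * spread * n ** (-0.2)


def kde_ise(X, Y, config: QualityConfig = QualityConfig()) -> float:
    """Integrated squared difference of two 1-D Gaussian KDEs."""
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if config.kde_bandwidth is not None:
        hx = hy = float(config.kde_bandwidth)
        if x.size < 1 or y.size < 1:
            raise ValueError("kde_ise requires non-empty samples")
    else:
        hx, hy = _silverman(x), _silverman(y)
    lo = min(x.min() - config.grid_pad_bandwidths * hx, y.min() - config.grid_pad_bandwidths * hy)
    hi = max(x.max() + config.grid_pad_bandwidths * hx, y.max() + config.grid_pad_bandwidths * hy)
    grid = np.linspace(lo, hi, config.n_grid)

    def kde(pts: np.ndarray, h: float) -> np.ndarray:
        z = (grid[:, None] - pts[None, :]) / h
        return np.exp(-0.5 * z * z).sum(axis=1) / (pts.size * h * np.sqrt(2 * np.pi))

    diff = kde(x, hx) - kde(y, hy)
    return float(np.trapezoid(diff * diff, grid))


def lmmd(X, Y, config: QualityConfig = QualityConfig()) -> float:
    """Mean of per-window MMDs over contiguous equal windows (remainder dropped)."""
    X, Y = _as2d(X), _as2d(Y)
    if len(X) != len(Y):
        raise ValueError("lmmd expects equally sized ordered sample sets")
    w = len(X) // config.n_windows
    if w < 2:
        raise ValueError("windows must contain at least two points each")
    vals = [
        mmd(X[i * w : (i + 1) * w], Y[i * w : (i + 1) * w], config)
        for i in range(config.n_windows)
    ]
    return float(np.mean(vals))


def knndc(X, Y, config: QualityConfig = QualityConfig()) -> float:
    """Mean over X of the average distance to the k nearest neighbours in Y."""
    X, Y = _as2d(X), _as2d(Y)
    k = config.k_neighbors
    if len(Y) < k:
        raise ValueError(f"knndc requires at least k={k} points in Y")
    nn = NearestNeighbors(n_neighbors=k).fit(Y)
    dist, _ = nn.kneighbors(X)
    return float(dist.mean())
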