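"""RMSE/CC/SSIM identities and the distribution-similarity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eit3d.metrics import MetricConfig, cc, evaluate_reconstruction, rmse, ssim
from eit3d.quality import QualityConfig, kde_ise, knndc, lmmd, mmd


# ---------------------------------------------------------------------------
# reconstruction metrics
# ---------------------------------------------------------------------------

def test_rmse_cases():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3), rel=1e-12)
    a = np.array([0.3, -1.2, 2.0])
    b = np.array([1.0, 0.0, -0.5])
    assert rmse(3 * a, 3 * b) == pytest.approx(3 * rmse(a, b), rel=1e-12)
    with pytest.raises(ValueError):
        rmse([1, 2], [1, 2, 3])


def test_cc_cases():
    p = np.array([1.0, 2.0, 3.0])
    assert cc(p, 2 * p + 3) == pytest.approx(1.0, rel=1e-12)
    assert cc(p, p[::-1]) == pytest.approx(-1.0, rel=1e-12)
    assert cc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, rel=1e-12)
    with pytest.raises(ValueError):
        cc([1, 1, 1], [1, 2, 3])


def test_ssim_identity_and_degenerate():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(50)
    assert ssim(a, a) == pytest.approx(1.0, rel=1e-12)
    assert ssim(np.full(5, 2.0), np.full(5, 2.0)) == pytest.approx(1.0)
    assert ssim(a + 0.5, a) < 1.0


def test_ssim_matches_direct_evaluation():
    P = np.array([0.1, 0.4, 0.2, 0.9])
    A = np.array([0.2, 0.5, 0.1, 0.7])
    L = A.max() - A.min()
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mp, ma = P.mean(), A.mean()
    cov = ((P - mp) * (A - ma)).mean()
    expected = ((2 * mp * ma + c1) * (2 * cov + c2)) / (
        (mp**2 + ma**2 + c1) * (P.var() + A.var() + c2)
    )
    assert ssim(P, A) == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_metrics_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    P = rng.standard_normal(40)
    A = rng.standard_normal(40)
    perm = rng.permutation(40)
    assert rmse(P[perm], A[perm]) == pytest.approx(rmse(P, A), rel=1e-12)
    assert cc(P[perm], A[perm]) == pytest.approx(cc(P, A), rel=1e-12)
    assert ssim(P[perm], A[perm]) == pytest.approx(ssim(P, A), rel=1e-12)


def test_metric_trends_under_increasing_noise():
    """More noise: RMSE up, CC and SSIM down, in the mean over 50 draws."""
    rng = np.random.default_rng(5)
    truth = np.abs(rng.standard_normal(300)) + 0.5
    levels = (0.01, 0.1, 0.5)
    means = []
    for lvl in levels:
        vals = np.array([
            [rmse(truth + lvl * np.random.default_rng(k).standard_normal(300), truth),
             cc(truth + lvl * np.random.default_rng(k).standard_normal(300), truth),
             ssim(truth + lvl * np.random.default_rng(k).standard_normal(300), truth)]
            for k in range(50)
        ]).mean(axis=0)
        means.append(vals)
    means = np.array(means)
    assert np.all(np.diff(means[:, 0]) > 0)  # rmse increasing
    assert np.all(np.diff(means[:, 1]) < 0)  # cc decreasing
    assert np.all(np.diff(means[:, 2]) < 0)  # ssim decreasing


def test_evaluate_reconstruction_bundles(mesh_coarse):
    from eit3d.fem import ConductivityField

    rng = np.random.default_rng(3)
    truth = ConductivityField(np.abs(rng.standard_normal(mesh_coarse.n_elements)) + 0.1,
                              mesh_coarse.mesh_hash)
    rep = evaluate_reconstruction(truth, truth, ipst_s=1.25)
    assert (rep.rmse, rep.cc, rep.ssim) == (0.0, pytest.approx(1.0), pytest.approx(1.0))
    assert rep.ipst_s == 1.25
    pred = ConductivityField(truth.values * 1.1, mesh_coarse.mesh_hash)
    rep2 = evaluate_reconstruction(pred, truth)
    assert rep2.rmse == pytest.approx(rmse(pred.values, truth.values))
    assert rep2.cc == pytest.approx(cc(pred.values, truth.values))
    assert rep2.ssim == pytest.approx(ssim(pred.values, truth.values))
    assert all(np.isfinite([rep2.rmse, rep2.cc, rep2.ssim]))


def test_evaluate_reconstruction_mesh_mismatch(mesh_coarse):
    from eit3d.fem import ConductivityField

    a = ConductivityField(np.ones(mesh_coarse.n_elements), mesh_coarse.mesh_hash)
    b = ConductivityField(np.ones(mesh_coarse.n_elements) * 2, "other-mesh")
    with pytest.raises(ValueError):
        evaluate_reconstruction(a, b)


# ---------------------------------------------------------------------------
# distribution-similarity statistics
# ---------------------------------------------------------------------------

def test_mmd_brute_force_two_point_sets():
    X = np.array([0.0, 1.0])
    Y = np.array([0.5, 2.0])
    h = 0.8
    cfg = QualityConfig(mmd_bandwidth=h)

    def k(a, b):
        return np.exp(-((a - b) ** 2) / (2 * h * h))

    xx = k(X[0], X[1])  # the single i != j term, counted twice / (n(n-1)=2)
    yy = k(Y[0], Y[1])
    xy = (k(X[0], Y[0]) + k(X[0], Y[1]) + k(X[1], Y[0]) + k(X[1], Y[1])) / 4
    expected = np.sqrt(max(xx + yy - 2 * xy, 0.0))
    assert mmd(X, Y, cfg) == pytest.approx(expected, rel=1e-12)


def test_mmd_symmetry_and_degenerate_zero():
    rng = np.random.default_rng(0)
    X = rng.standard_normal(20)
    Y = rng.standard_normal(25) + 0.5
    assert mmd(X, Y) == pytest.approx(mmd(Y, X), rel=1e-12)
    Z = np.full(10, 3.0)
    assert mmd(Z, np.full(12, 3.0), QualityConfig(mmd_bandwidth=1.0)) == 0.0
    with pytest.raises(ValueError):
        mmd([1.0], Y)


def test_kde_ise_identity_and_nonnegative():
    rng = np.random.default_rng(1)
    X = rng.standard_normal(60)
    assert kde_ise(X, X.copy()) <= 1e-8
    Y = rng.standard_normal(60) + 2.0
    assert kde_ise(X, Y) >= 0


def test_kde_ise_separated_kernels_closed_form():
    """Two far-apart single-point samples: ISE -> 1/(h*sqrt(pi))."""
    h = 0.3
    cfg = QualityConfig(kde_bandwidth=h, n_grid=4096)
    val = kde_ise([0.0], [100.0], cfg)
    assert val == pytest.approx(1.0 / (h * np.sqrt(np.pi)), rel=0.02)


def test_kde_degenerate_sample_warns():
    with pytest.warns(UserWarning, match="bandwidth"):
        kde_ise(np.full(10, 1.0), np.random.default_rng(0).standard_normal(10))


def test_lmmd_single_window_equals_mmd():
    rng = np.random.default_rng(2)
    X = rng.standard_normal(30)
    Y = rng.standard_normal(30) + 1.0
    cfg = QualityConfig(n_windows=1, mmd_bandwidth=1.0)
    assert lmmd(X, Y, cfg) == pytest.approx(mmd(X, Y, cfg), rel=1e-12)


def test_lmmd_two_window_oracle():
    X = np.array([0.0, 1.0, 5.0, 6.0])
    Y = np.array([0.5, 2.0, 5.5, 7.0])
    cfg = QualityConfig(n_windows=2, mmd_bandwidth=0.9)
    expected = 0.5 * (mmd(X[:2], Y[:2], cfg) + mmd(X[2:], Y[2:], cfg))
    assert lmmd(X, Y, cfg) == pytest.approx(expected, rel=1e-12)
    assert lmmd(np.full(8, 2.0), np.full(8, 2.0), QualityConfig(n_windows=2, mmd_bandwidth=1.0)) == 0.0


def test_lmmd_window_validation():
    with pytest.raises(ValueError):
        lmmd(np.arange(5.0), np.arange(5.0), QualityConfig(n_windows=5))


def test_knndc_hand_cases():
    assert knndc([0.0], [3.0], QualityConfig(k_neighbors=1)) == pytest.approx(3.0)
    # neighbours at distances 1 and 3 with k=2 -> mean 2
    assert knndc([0.0], [1.0, -3.0, 10.0], QualityConfig(k_neighbors=2)) == pytest.approx(2.0)
    rng = np.random.default_rng(4)
    X = rng.standard_normal(15)
    Y = rng.standard_normal(20)
    perm = rng.permutation(20)
    cfg = QualityConfig(k_neighbors=3)
    assert knndc(X, Y[perm], cfg) == pytest.approx(knndc(X, Y, cfg), rel=1e-12)
    with pytest.raises(ValueError):
        knndc(X, Y[:2], QualityConfig(k_neighbors=5))
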