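"""Noise injection, detection-limit accounting, and sample-set persistence."""

import numpy as np
import pytest

from eit3d.dataset import (
    DatasetFormatError,
    SampleSet,
    generate_sampleset,
    load_sampleset,
    save_sampleset,
    split_sampleset,
)
from eit3d.fem import ConductivityField
from eit3d.noise import NoiseSpec, add_noise, detection_report, noise_sigma
from eit3d.phantoms import PhantomSampler
from eit3d.protocol import VoltageFrame, build_protocol, extract_frame

PATTERN, SCHEME = build_protocol()


def test_add_noise_passthrough_and_determinism(frame_default):
    clean = add_noise(frame_default, NoiseSpec(snr_db=None))
    assert np.array_equal(clean.values, frame_default.values)
    n1 = add_noise(frame_default, NoiseSpec(40.0, seed=5))
    n2 = add_noise(frame_default, NoiseSpec(40.0, seed=5))
    assert np.array_equal(n1.values, n2.values)
    n3 = add_noise(frame_default, NoiseSpec(40.0, seed=6))
    assert not np.array_equal(n1.values, n3.values)


def test_add_noise_rejects_zero_frame():
    with pytest.raises(ValueError):
        add_noise(VoltageFrame(np.zeros(2160)), NoiseSpec(40.0))


def test_realized_snr_within_half_db(frame_default):
    """Mean realized SNR over 200 noisy frames is within +-0.5 dB of target."""
    target = 40.0
    sig_pow = float(np.mean(frame_default.values**2))
    snrs = []
    for seed in range(200):
        noisy = add_noise(frame_default, NoiseSpec(target, seed=seed))
        noise_pow = float(np.mean((noisy.values - frame_default.values) ** 2))
        snrs.append(10 * np.log10(sig_pow / noise_pow))
    assert abs(np.mean(snrs) - target) < 0.5


def test_noise_is_additive_with_expected_moments(frame_default):
    """Pooled noise over many frames has mean -> 0 and std -> sigma within 2%."""
    spec_sigma = noise_sigma(frame_default, NoiseSpec(40.0))
    pooled = []
    for seed in range(47):  # 47 * 2160 > 1e5 values
        noisy = add_noise(frame_default, NoiseSpec(40.0, seed=seed))
        pooled.append(noisy.values - frame_default.values)
    pooled = np.concatenate(pooled)
    assert pooled.size > 1e5
    assert abs(pooled.std() - spec_sigma) / spec_sigma < 0.02
    assert abs(pooled.mean()) < 0.02 * spec_sigma


def test_detection_report_hand_case():
    """Frame (1, 2, 10) with unit noise std: threshold 3, one pass."""
    frame = VoltageFrame(np.array([1.0, 2.0, 10.0]))
    rms = float(np.sqrt(np.mean(frame.values**2)))
    spec = NoiseSpec(snr_db=20 * np.log10(rms), seed=0)  # sigma_noise = 1 exactly
    rep = detection_report(frame, spec)
    assert rep.threshold == pytest.approx(3.0, rel=1e-12)
    assert rep.n_pass == 1
    assert rep.proportion == pytest.approx(1 / 3)


def test_detection_report_edge_cases():
    z = VoltageFrame(np.zeros(10))
    rep = detection_report(z, NoiseSpec(40.0))
    assert rep.n_pass == 0
    nonzero = VoltageFrame(np.array([0.0, 1e-9, -2e-9]))
    rep = detection_report(nonzero, NoiseSpec(None))
    assert rep.threshold == 0.0
    assert rep.n_pass == 2


def test_detection_proportion_monotone_in_snr(ctx_default, mesh_default, protocol):
    from eit3d.phantoms import AcrylicPhantomSpec, Shape, acrylic_field

    pattern, scheme = protocol
    fld = acrylic_field(mesh_default, AcrylicPhantomSpec((Shape("sphere", (1.0, 0.5, 4.0), (1.3,)),)))
    frame = extract_frame(ctx_default.solve(fld, pattern), scheme)
    props = []
    for snr in (20.0, 30.0, 40.0, 50.0, 60.0):
        rep = detection_report(frame, NoiseSpec(snr))
        assert rep.n_pass == rep.proportion * rep.n_total
        props.append(rep.proportion)
    assert all(b >= a for a, b in zip(props, props[1:]))
    assert props[-1] > props[0]


@pytest.fixture(scope="module")
def small_sampleset(mesh_default, cem, protocol, ctx_default):
    sampler = PhantomSampler(seed=99)
    return generate_sampleset(
        mesh_default, cem, protocol, sampler, n=10, noise=NoiseSpec(40.0, seed=1),
        context=ctx_default,
    )


def test_generate_sampleset_counts_and_metadata(small_sampleset, mesh_default):
    s = small_sampleset
    assert len(s) == 10
    assert s.frames_clean.shape == (10, 2160)
    assert s.manifest["mesh_hash"] == mesh_default.mesh_hash
    assert len(s.specs) == 10


def test_sampleset_clean_frames_rederivable(small_sampleset, ctx_default, mesh_default, protocol):
    pattern, scheme = protocol
    i = 3
    fld = ConductivityField(small_sampleset.sigma[i], mesh_default.mesh_hash)
    v = extract_frame(ctx_default.solve(fld, pattern), scheme).values
    ref = small_sampleset.frames_clean[i]
    assert np.abs(v - ref).max() <= 1e-10 * np.abs(ref).max()


def test_generate_sampleset_deterministic(mesh_default, cem, protocol, ctx_default):
    kw = dict(n=3, noise=NoiseSpec(40.0, seed=2), context=ctx_default)
    a = generate_sampleset(mesh_default, cem, protocol, PhantomSampler(seed=5), **kw)
    b = generate_sampleset(mesh_default, cem, protocol, PhantomSampler(seed=5), **kw)
    assert np.array_equal(a.frames_noisy, b.frames_noisy)
    assert np.array_equal(a.sigma, b.sigma)


def _synthetic_set(n, L=12, N=7):
    rng = np.random.default_rng(0)
    from eit3d.phantoms import MaizePhantomSpec

    return SampleSet(
        frames_clean=rng.standard_normal((n, L)),
        frames_noisy=rng.standard_normal((n, L)),
        sigma=np.abs(rng.standard_normal((n, N))) + 0.1,
        specs=[MaizePhantomSpec() for _ in range(n)],
        manifest={"mesh_hash": "x", "protocol_hash": "y", "schema_version": 1},
    )


def test_split_sizes_8_to_2():
    s = split_sampleset(_synthetic_set(20000), ratio=0.8, seed=0)
    assert s.train_indices.size == 16000
    assert s.val_indices.size == 4000
    s10 = split_sampleset(_synthetic_set(10), ratio=0.8, seed=0)
    assert s10.train_indices.size == 8
    assert s10.val_indices.size == 2


def test_split_is_a_partition():
    s = split_sampleset(_synthetic_set(101), ratio=0.7, seed=3)
    union = np.union1d(s.train_indices, s.val_indices)
    assert np.array_equal(union, np.arange(101))
    assert np.intersect1d(s.train_indices, s.val_indices).size == 0


def test_split_validation():
    with pytest.raises(ValueError):
        split_sampleset(_synthetic_set(10), ratio=1.2)
    with pytest.raises(ValueError):
        split_sampleset(_synthetic_set(1), ratio=0.5)


def test_sampleset_io_round_trip(tmp_path, small_sampleset):
    split_sampleset(small_sampleset, 0.8, seed=4)
    path = tmp_path / "set.h5"
    save_sampleset(small_sampleset, path)
    back = load_sampleset(path)
    assert np.array_equal(back.frames_clean, small_sampleset.frames_clean)
    assert np.array_equal(back.frames_noisy, small_sampleset.frames_noisy)
    assert np.array_equal(back.sigma, small_sampleset.sigma)
    assert np.array_equal(back.split, small_sampleset.split)
    assert back.specs == small_sampleset.specs
    assert back.manifest == small_sampleset.manifest


def test_sampleset_io_rejects_bad_schema(tmp_path):
    import h5py

    path = tmp_path / "bad.h5"
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = 999
    with pytest.raises(DatasetFormatError):
        load_sampleset(path)
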