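"""Adjacent-protocol combinatorics and the feature-map reconfiguration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eit3d.protocol import (
    FRAME_LEN,
    FeatureMap,
    VoltageFrame,
    build_protocol,
    extract_frame,
    featuremap_to_frame,
    frame_to_featuremap,
    load_frame_csv,
    protocol_hash,
    save_frame_csv,
)

PATTERN, SCHEME = build_protocol()


def test_protocol_counts():
    assert PATTERN.n_excitations == 48
    assert all(len(p) == 45 for p in SCHEME.pairs)
    assert SCHEME.frame_length == 2160


def test_drive_order_within_rings():
    assert PATTERN.drive_pairs[:3] == ((2, 1), (3, 2), (4, 3))
    assert PATTERN.drive_pairs[15] == (1, 16)
    assert PATTERN.drive_pairs[16] == (18, 17)
    assert PATTERN.drive_pairs[31] == (17, 32)
    assert PATTERN.drive_pairs[32] == (34, 33)
    assert PATTERN.drive_pairs[47] == (33, 48)


# the entries of the canonical measurement matrix that are printed explicitly:
# (excitation index, measurement position) -> (out1, out2)
LITERAL_ENTRIES = {
    # drive (2,1): own ring 3..15, then rings B and C from local pair 1
    (0, 0): (3, 4), (0, 1): (4, 5), (0, 12): (15, 16),
    (0, 13): (17, 18), (0, 14): (18, 19), (0, 28): (32, 17),
    (0, 29): (33, 34), (0, 30): (34, 35), (0, 44): (48, 33),
    # drive (3,2)
    (1, 0): (4, 5), (1, 1): (5, 6), (1, 12): (16, 1),
    (1, 13): (18, 19), (1, 14): (19, 20), (1, 28): (17, 18),
    (1, 29): (34, 35), (1, 30): (35, 36), (1, 44): (33, 34),
    # drive (16,15)
    (14, 0): (1, 2), (14, 1): (2, 3), (14, 12): (13, 14),
    (14, 13): (31, 32), (14, 14): (32, 17), (14, 28): (30, 31),
    (14, 29): (47, 48), (14, 30): (48, 33), (14, 44): (46, 47),
    # drive (18,17): ring A block first, own-ring block second
    (16, 0): (1, 2), (16, 1): (2, 3), (16, 15): (16, 1),
    (16, 16): (19, 20), (16, 17): (20, 21), (16, 28): (31, 32),
    (16, 29): (33, 34), (16, 30): (34, 35), (16, 44): (48, 33),
    # drive (19,18)
    (17, 0): (2, 3), (17, 1): (3, 4), (17, 15): (1, 2),
    (17, 16): (20, 21), (17, 17): (21, 22), (17, 28): (32, 17),
    (17, 29): (34, 35), (17, 30): (35, 36), (17, 44): (33, 34),
    # drive (17,32)
    (31, 0): (16, 1), (31, 1): (1, 2), (31, 15): (15, 16),
    (31, 16): (18, 19), (31, 17): (19, 20), (31, 28): (30, 31),
    (31, 29): (48, 33), (31, 30): (33, 34), (31, 44): (47, 48),
    # drive (34,33)
    (32, 0): (1, 2), (32, 1): (2, 3), (32, 15): (16, 1),
    (32, 16): (17, 18), (32, 17): (18, 19), (32, 31): (32, 17),
    (32, 32): (35, 36), (32, 33): (36, 37), (32, 44): (47, 48),
    # drive (33,48)
    (47, 0): (16, 1), (47, 1): (1, 2), (47, 15): (15, 16),
    (47, 16): (32, 17), (47, 17): (17, 18), (47, 31): (31, 32),
    (47, 32): (34, 35), (47, 33): (35, 36), (47, 44): (46, 47),
}


@pytest.mark.parametrize("key,expected", sorted(LITERAL_ENTRIES.items()))
def test_measurement_matrix_literal_entries(key, expected):
    e, m = key
    assert SCHEME.pairs[e][m] == expected


def test_no_measurement_touches_drive_pair():
    for (in1, in2), meas in zip(PATTERN.drive_pairs, SCHEME.pairs):
        for out1, out2 in meas:
            assert {out1, out2}.isdisjoint({in1, in2})


def test_exclusion_counts_per_ring():
    # exactly 3 within-ring pairs are excluded (drive + its two neighbours)
    for e, ((in1, in2), meas) in enumerate(zip(PATTERN.drive_pairs, SCHEME.pairs)):
        ring = (in2 - 1) // 16
        per_ring = [0, 0, 0]
        for out1, _ in meas:
            per_ring[(out1 - 1) // 16] += 1
        assert per_ring[ring] == 13
        assert sum(per_ring) == 45
        assert sorted(per_ring) == [13, 16, 16]


def test_extract_frame_positions_and_zero_case(ctx_default, homog_default, protocol):
    pattern, scheme = protocol
    pots = ctx_default.solve(homog_default, pattern)
    frame = extract_frame(pots, scheme)
    U = pots.electrode_potentials
    # spot-check the differential convention at a few frame positions
    for e, m in [(0, 0), (5, 17), (47, 44)]:
        out1, out2 = scheme.pairs[e][m]
        assert frame.values[e * 45 + m] == U[e, out1 - 1] - U[e, out2 - 1]

    class Flat:
        electrode_potentials = np.ones((48, 48))

    assert np.all(extract_frame(Flat(), scheme).values == 0.0)


def test_featuremap_layout_and_round_trip():
    frame = VoltageFrame(np.arange(FRAME_LEN, dtype=float))
    fmap = frame_to_featuremap(frame)
    assert fmap.matrix.shape == (45, 48)
    # first frame value (drive (2,1), measurement (3,4)) lands at (0, 0)
    assert fmap.matrix[0, 0] == 0.0
    # column e of the transposed map is excitation e's 45 measurements
    assert np.all(fmap.matrix[:, 1] == np.arange(45, 90))
    back = featuremap_to_frame(fmap)
    assert np.array_equal(back.values, frame.values)


def test_featuremap_shape_errors():
    with pytest.raises(ValueError):
        frame_to_featuremap(VoltageFrame(np.zeros(100)))
    with pytest.raises(ValueError):
        FeatureMap(np.zeros((48, 45)))


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_featuremap_bijection_random(seed):
    vals = np.random.default_rng(seed).standard_normal(FRAME_LEN)
    out = featuremap_to_frame(frame_to_featuremap(VoltageFrame(vals)))
    assert np.array_equal(out.values, vals)


def test_frame_csv_round_trip(tmp_path):
    vals = np.random.default_rng(7).standard_normal(FRAME_LEN)
    frame = VoltageFrame(vals)
    path = tmp_path / "frame.csv"
    save_frame_csv(frame, path, proto_hash=protocol_hash(PATTERN, SCHEME))
    back = load_frame_csv(path)
    assert np.allclose(back.values, vals, rtol=0, atol=0)
    assert back.metadata["protocol_hash"] == protocol_hash(PATTERN, SCHEME)
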