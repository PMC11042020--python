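"""Adjacent stimulation protocol for the 48-electrode, three-ring cylindrical array.

Electrodes are numbered 1..48: ring A = 1..16, ring B = 17..32, ring C = 33..48,
each ring a circle of 16 equally spaced electrodes. Current is driven through
ring-adjacent pairs, cycling through all 16 positions of each ring in turn
(48 excitations). For every excitation, 45 differential voltages are recorded
on adjacent pairs that do not touch the driven electrodes: 13 pairs in the
drive's own ring and 16 in each of the other two rings, 48*45 = 2,160 values
per frame.

Ordering convention (the canonical measurement matrix):

* within a ring, adjacent pair ``j`` (1-based, j = 1..16) is the electrode pair
  ``(base + j, base + j%16 + 1)`` and the recorded value is
  ``v = phi(out1) - phi(out2)`` in that subscript order;
* excitation ``k`` of a ring drives pair ``(local k+1, local k)``, i.e.
  (2,1), (3,2), ..., (16,15), (1,16) for ring A, then rings B and C likewise;
* the 45 measurements are listed ring-block by ring-block in A, B, C order;
  the drive's own ring contributes pairs ``k+2 .. k+14`` (cyclic, 13 pairs,
  skipping the drive pair and its two electrode-sharing neighbours), every
  other ring contributes all 16 pairs starting from local index ``k``.

The frame is stored excitation-major; ``frame_to_featuremap`` reshapes it into
the 48x45 excitation-by-measurement matrix and transposes to the 45x48
single-channel feature map consumed by the reconstruction network.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

N_ELECTRODES = 48
N_RINGS = 3
N_PER_RING = 16
N_EXCITATIONS = 48
N_MEAS_PER_EXC = 45
FRAME_LEN = N_EXCITATIONS * N_MEAS_PER_EXC  # 2,160


@dataclass(frozen=True)
class ExcitationPattern:
    """Ordered drive pairs ``(in1, in2)``; +I is injected at in1, -I at in2."""

    drive_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.drive_pairs) != N_EXCITATIONS:
            raise ValueError(f"expected {N_EXCITATIONS} drive pairs, got {len(self.drive_pairs)}")
        for in1, in2 in self.drive_pairs:
            if not (1 <= in1 <= N_ELECTRODES and 1 <= in2 <= N_ELECTRODES):
                raise ValueError(f"electrode index out of range in drive pair ({in1}, {in2})")
            if (in1 - 1) // N_PER_RING != (in2 - 1) // N_PER_RING:
                raise ValueError(f"drive pair ({in1}, {in2}) spans two rings")

    @property
    def n_excitations(self) -> int:
        return len(self.drive_pairs)


@dataclass(frozen=True)
class MeasurementScheme:
    """Per-excitation ordered measurement pairs ``(out1, out2)``."""

    pairs: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_excitations(self) -> int:
        return len(self.pairs)

    @property
    def frame_length(self) -> int:
        return sum(len(p) for p in self.pairs)


def _ring_pair(ring: int, j: int) -> tuple[int, int]:
    """Adjacent pair j (1-based, cyclic) of ring 0/1/2, as electrode numbers."""
    base = ring * N_PER_RING
    j = (j - 1) % N_PER_RING + 1
    return (base + j, base + j % N_PER_RING + 1)


def build_protocol() -> tuple[ExcitationPattern, MeasurementScheme]:
    """Build the canonical 48-excitation / 45-measurement adjacent protocol."""
    drives: list[tuple[int, int]] = []
    scheme: list[tuple[tuple[int, int], ...]] = []
    for ring in range(N_RINGS):
        for k in range(1, N_PER_RING + 1):
            lo, hi = _ring_pair(ring, k)  # drive pair electrodes (local k, k+1)
            drives.append((hi, lo))  # printed order: (k+1, k)
            meas: list[tuple[int, int]] = []
            for rho in range(N_RINGS):
                if rho == ring:
                    js = [k + 2 + i for i in range(13)]
                else:
                    js = [k + i for i in range(16)]
                meas.extend(_ring_pair(rho, j) for j in js)
            scheme.append(tuple(meas))
    return ExcitationPattern(tuple(drives)), MeasurementScheme(tuple(scheme))


def protocol_hash(pattern: ExcitationPattern, scheme: MeasurementScheme) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(pattern.drive_pairs, dtype=np.int64).tobytes())
    for p in scheme.pairs:
        h.update(np.asarray(p, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


@dataclass
class VoltageFrame:
    """Excitation-major vector of differential boundary voltages (V)."""

    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("frame values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FeatureMap:
    """45 x 48 single-channel reconfiguration of a voltage frame."""

    matrix: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_MEAS_PER_EXC, N_EXCITATIONS):
            raise ValueError(
                f"feature map must be {N_MEAS_PER_EXC} x {N_EXCITATIONS}, got {self.matrix.shape}"
            )


def extract_frame(potentials, scheme: MeasurementScheme, metadata: dict | None = None) -> VoltageFrame:
    """Differential voltages from solved electrode potentials, excitation-major.

    ``potentials`` must expose ``electrode_potentials`` of shape
    (n_excitations, 48) solved under the matching excitation pattern.
    """
    U = np.asarray(potentials.electrode_potentials, dtype=float)
    if U.shape[0] != scheme.n_excitations:
        raise ValueError(
            f"potential set has {U.shape[0]} excitations, scheme expects {scheme.n_excitations}"
        )
    vals = np.empty(scheme.frame_length)
    pos = 0
    for e, meas in enumerate(scheme.pairs):
        for out1, out2 in meas:
            vals[pos] = U[e, out1 - 1] - U[e, out2 - 1]
            pos += 1
    meta = dict(metadata or {})
    return VoltageFrame(vals, meta)


def frame_to_featuremap(frame: VoltageFrame) -> FeatureMap:
    """Reshape excitation-major frame to 48 x 45 and transpose to 45 x 48."""
    if len(frame) != FRAME_LEN:
        raise ValueError(f"expected frame of length {FRAME_LEN}, got {len(frame)}")
    mat = frame.values.reshape(N_EXCITATIONS, N_MEAS_PER_EXC).T
    return FeatureMap(mat.copy(), dict(frame.metadata))


def featuremap_to_frame(fmap: FeatureMap) -> VoltageFrame:
    """Exact inverse of :func:`frame_to_featuremap`."""
    vals = fmap.matrix.T.reshape(FRAME_LEN).copy()
    return VoltageFrame(vals, dict(fmap.metadata))


def save_frame_csv(frame: VoltageFrame, path, proto_hash: str | None = None) -> None:
    """One value per line; ``#``-prefixed header carries the protocol hash."""
    with open(path, "w") as f:
        f.write(f"# eit3d voltage frame, n={len(frame)}\n")
        if proto_hash:
            f.write(f"# protocol_hash={proto_hash}\n")
        for v in frame.values:
            f.write(f"{v:.17g}\n")


def load_frame_csv(path) -> VoltageFrame:
    meta: dict = {}
    vals: list[float] = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "protocol_hash=" in line:
                    meta["protocol_hash"] = line.split("protocol_hash=")[1].strip()
                continue
            vals.append(float(line))
    return VoltageFrame(np.asarray(vals), meta)
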