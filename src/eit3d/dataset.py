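"""Voltage-conductivity sample sets: generation, splitting, HDF5 persistence.

A sample is (clean frame, noisy frame, per-element conductivity, phantom
spec). The manifest records the mesh hash, protocol hash, noise settings and
master seed so every sample is re-derivable: re-solving the forward problem
on a stored conductivity field reproduces the stored clean frame bit-for-bit
up to solver precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .fem import CEMParams, ConductivityField, FEMContext
from .mesh import Mesh
from .noise import NoiseSpec, add_noise
from .phantoms import (
    AcrylicPhantomSpec,
    MaizePhantomSpec,
    PhantomSampler,
    Shape,
    acrylic_field,
    maize_field,
)
from .protocol import ExcitationPattern, MeasurementScheme, VoltageFrame, extract_frame, protocol_hash

SCHEMA_VERSION = 1


class DatasetFormatError(ValueError):
    pass


def _spec_to_json(spec) -> str:
    d = dataclasses.asdict(spec)
    d["__kind__"] = type(spec).__name__
    return json.dumps(d)


def _spec_from_json(s: str):
    d = json.loads(s)
    kind = d.pop("__kind__")
    if kind == "AcrylicPhantomSpec":
        shapes = tuple(
            Shape(sh["kind"], tuple(sh["center"]), tuple(sh["size"])) for sh in d["shapes"]
        )
        return AcrylicPhantomSpec(shapes, d["sigma_background"], d["sigma_inclusion"])
    if kind == "MaizePhantomSpec":
        d["center"] = tuple(d["center"])
        d["bs"] = tuple(d["bs"])
        return MaizePhantomSpec(**d)
    raise DatasetFormatError(f"unknown phantom spec kind {kind!r}")


@dataclass
class SampleSet:
    frames_clean: np.ndarray  # (n, L)
    frames_noisy: np.ndarray  # (n, L)
    sigma: np.ndarray  # (n, N), S/m
    specs: list  # phantom specs
    manifest: dict = field(default_factory=dict)
    split: np.ndarray | None = None  # 0 = train, 1 = validation

    def __post_init__(self) -> None:
        n = self.frames_clean.shape[0]
        if not (self.frames_noisy.shape[0] == self.sigma.shape[0] == len(self.specs) == n):
            raise ValueError("sample arrays must share their leading dimension")

    def __len__(self) -> int:
        return self.frames_clean.shape[0]

    @property
    def train_indices(self) -> np.ndarray:
        if self.split is None:
            raise ValueError("sample set has not been split")
        return np.nonzero(self.split == 0)[0]

    @property
    def val_indices(self) -> np.ndarray:
        if self.split is None:
            raise ValueError("sample set has not been split")
        return np.nonzero(self.split == 1)[0]


def generate_sampleset(
    mesh: Mesh,
    cem: CEMParams,
    protocol: tuple[ExcitationPattern, MeasurementScheme],
    sampler: PhantomSampler,
    n: int,
    noise: NoiseSpec,
    phantom_kind: str = "acrylic",
    context: FEMContext | None = None,
) -> SampleSet:
    """Draw n phantoms, solve each forward problem, record clean/noisy frames."""
    pattern, scheme = protocol
    ctx = context if context is not None else FEMContext(mesh, cem)
    L = scheme.frame_length
    frames_clean = np.empty((n, L))
    frames_noisy = np.empty((n, L))
    sigma = np.empty((n, mesh.n_elements))
    specs = []
    noise_rng = np.random.default_rng(noise.seed)
    i = 0
    attempts = 0
    while i < n:
        attempts += 1
        if attempts > 10 * max(n, 1):
            raise RuntimeError("too many failed forward solves while generating samples")
        spec = sampler.sample(phantom_kind)
        fld = acrylic_field(mesh, spec) if phantom_kind == "acrylic" else maize_field(mesh, spec)
        if np.all(fld.values == fld.values[0]):
            # inclusion missed every element centroid: a mislabeled homogeneous
            # sample; redraw (count preserved) like a failed forward solve
            continue
        try:
            pots = ctx.solve(fld, pattern)
        except RuntimeError:
            continue  # redraw, count preserved
        clean = extract_frame(pots, scheme)
        sample_noise = NoiseSpec(noise.snr_db, int(noise_rng.integers(0, 2**31 - 1)))
        noisy = add_noise(clean, sample_noise)
        frames_clean[i] = clean.values
        frames_noisy[i] = noisy.values
        sigma[i] = fld.values
        specs.append(spec)
        i += 1
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "mesh_hash": mesh.mesh_hash,
        "protocol_hash": protocol_hash(pattern, scheme),
        "snr_db": noise.snr_db,
        "noise_seed": noise.seed,
        "sampler_seed": sampler.seed,
        "phantom_kind": phantom_kind,
        "n_elements": mesh.n_elements,
    }
    return SampleSet(frames_clean, frames_noisy, sigma, specs, manifest)


def split_sampleset(sset: SampleSet, ratio: float = 0.8, seed: int = 0) -> SampleSet:
    """Seeded random train/validation partition; train size = floor(ratio*n)."""
    if not (0 < ratio < 1):
        raise ValueError("split ratio must lie strictly between 0 and 1")
    n = len(sset)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * n))
    perm = np.random.default_rng(seed).permutation(n)
    split = np.ones(n, dtype=np.int8)
    split[perm[:n_train]] = 0
    sset.split = split
    sset.manifest["split_ratio"] = ratio
    sset.manifest["split_seed"] = seed
    return sset


def save_sampleset(sset: SampleSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["manifest"] = json.dumps(sset.manifest)
        f.create_dataset("frames_clean", data=sset.frames_clean)
        f.create_dataset("frames_noisy", data=sset.frames_noisy)
        f.create_dataset("sigma", data=sset.sigma)
        f.create_dataset(
            "specs", data=np.array([_spec_to_json(s) for s in sset.specs], dtype=object),
            dtype=h5py.string_dtype(),
        )
        if sset.split is not None:
            f.create_dataset("split", data=sset.split)


def load_sampleset(path) -> SampleSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise DatasetFormatError(
                f"unsupported sample-set schema version {f.attrs.get('schema_version')!r}"
            )
        manifest = json.loads(f.attrs["manifest"])
        specs = [_spec_from_json(s.decode() if isinstance(s, bytes) else s) for s in f["specs"][()]]
        sset = SampleSet(
            frames_clean=f["frames_clean"][()],
            frames_noisy=f["frames_noisy"][()],
            sigma=f["sigma"][()],
            specs=specs,
            manifest=manifest,
        )
        if "split" in f:
            sset.split = f["split"][()]
    return sset
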