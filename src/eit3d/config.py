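"""Run configuration: YAML-backed, schema-validated, with Table-2 style defaults.

The default configuration reproduces the simulation environment used
throughout: 8 cm x 5 cm cylinder, 3 rings of 16 electrodes, 350 uS/cm saline
background, 0.0001 uS/cm acrylic inclusions, SNR set {30, 40, 50} dB.
Unknown keys are rejected. A single master seed fans out to per-component
seeds through a stable hash so partial pipelines stay reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CylinderConfig(_Strict):
    radius_cm: float = 5.0
    height_cm: float = 8.0
    ring_heights_cm: tuple[float, float, float] = (2.0, 4.0, 6.0)
    electrodes_per_ring: int = 16
    electrode_angular_width_deg: float = 10.0
    electrode_height_cm: float = 0.5
    refinement: int = 2


class CEMConfig(_Strict):
    contact_impedance_ohm_m2: float = 1e-4
    current_amplitude_A: float = 1e-3


class SamplerConfig(_Strict):
    phantom_kind: str = "acrylic"
    sigma_background_uS_cm: float = 350.0
    sigma_inclusion_uS_cm: float = 0.0001
    center_radial_frac: float = 0.6
    center_axial_frac: tuple[float, float] = (0.2, 0.8)
    size_range_cm: tuple[float, float] = (0.8, 1.6)
    a_range: tuple[float, float] = (0.0, 0.2)


class NoiseConfig(_Strict):
    snr_db: float | None = 40.0
    snr_set_db: tuple[float, ...] = (30.0, 40.0, 50.0)


class NetworkConfig(_Strict):
    scale: str = "reduced"  # "full" -> (3,4,6,3)/(64..512), "reduced" -> desk scale
    epochs: int = 50
    batch_size: int = 32
    base_lr: float = 1e-4
    alpha: float = 100.0
    lr_factor: float = 0.5
    lr_patience: int = 5
    weight_decay: float = 0.0


class GNConfigModel(_Strict):
    lam: float = 1e-3
    prior: str = "identity"
    max_iters: int = 10


class QualityConfigModel(_Strict):
    n_windows: int = 10
    k_neighbors: int = 5


class RunConfig(_Strict):
    cylinder: CylinderConfig = Field(default_factory=CylinderConfig)
    cem: CEMConfig = Field(default_factory=CEMConfig)
    sampler: SamplerConfig = Field(default_factory=SamplerConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    gn: GNConfigModel = Field(default_factory=GNConfigModel)
    quality: QualityConfigModel = Field(default_factory=QualityConfigModel)
    n_samples: int = 100
    split_ratio: float = 0.8
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; command-line overrides win."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section, _, leaf = key.partition(".")
        if leaf:
            data.setdefault(section, {})[leaf] = value
        else:
            data[key] = value
    return RunConfig(**data)


def derive_seed(master: int, name: str) -> int:
    """Stable per-component seed below 2**31."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)
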