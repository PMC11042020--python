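"""SNR-controlled Gaussian measurement noise and the detection-limit report.

The SNR convention is frame-wise on RMS amplitude: a target of ``snr_db``
adds i.i.d. zero-mean Gaussian noise with standard deviation
``RMS(frame) * 10**(-snr_db/20)``. A measurement is deemed detectable when
its magnitude exceeds the noise mean plus three noise standard deviations
(the mean is zero here, so the threshold is ``3 * sigma_noise``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import VoltageFrame


@dataclass(frozen=True)
class NoiseSpec:
    snr_db: float | None = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite when present")


@dataclass(frozen=True)
class DetectionReport:
    n_pass: int
    n_total: int
    threshold: float  # V

    @property
    def proportion(self) -> float:
        return self.n_pass / self.n_total


def noise_sigma(frame: VoltageFrame, spec: NoiseSpec) -> float:
    """Noise standard deviation implied by the frame RMS and the target SNR."""
    if spec.snr_db is None:
        return 0.0
    rms = float(np.sqrt(np.mean(frame.values**2)))
    if rms == 0.0:
        raise ValueError("SNR-scaled noise is undefined for an all-zero frame")
    return rms * 10.0 ** (-spec.snr_db / 20.0)


def add_noise(frame: VoltageFrame, spec: NoiseSpec) -> VoltageFrame:
    """Additive Gaussian noise at the configured SNR; deterministic under seed."""
    if spec.snr_db is None:
        return VoltageFrame(frame.values.copy(), dict(frame.metadata))
    sigma = noise_sigma(frame, spec)
    rng = np.random.default_rng(spec.seed)
    noisy = frame.values + rng.normal(0.0, sigma, size=frame.values.size)
    meta = dict(frame.metadata)
    meta.update(snr_db=spec.snr_db, noise_seed=spec.seed, noisy=True)
    return VoltageFrame(noisy, meta)


def detection_report(frame: VoltageFrame, spec: NoiseSpec) -> DetectionReport:
    """Count measurements whose magnitude exceeds mean + 3 std of the noise."""
    if spec.snr_db is None:
        thr = 0.0
    else:
        thr = 3.0 * noise_sigma(frame, spec) if np.any(frame.values != 0) else 0.0
    n_pass = int(np.count_nonzero(np.abs(frame.values) > thr))
    return DetectionReport(n_pass=n_pass, n_total=frame.values.size, threshold=thr)
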