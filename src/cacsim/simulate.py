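"""Scan acquisition simulation: kVp-dependent attenuation scaling and noise.

The three study protocols are emulated as follows.  Starting from the
noiseless 120 kVp reference volume, calcium voxels are multiplied by the
voltage's calcium scale (the ratio encoded by the adapted thresholds:
1.3625 at 80 kVp, 1.5925 at 70 kVp), all other voxels by the blood-signal
ratio (1.0515 / 1.0948), then independent Gaussian noise is added and the
result is quantized to integer HU.

The noise magnitude follows a multiplicative model

    sigma(kvp, mA, bmi) = sigma_ref * gain(kvp) * sqrt(200 / mA)
                          * exp(beta * (bmi - 26))

with sigma_ref = 28.1 HU (the 120 kVp / 200 mA reference at median BMI) and
per-kVp gains calibrated so the study's mean low-kVp tube currents
(460.1 / 460.6 mA) reproduce the study's mean noise (27.7 / 28.7 HU) at
BMI 26.  The scanner's proprietary noise-index current selection is
replaced by closed-form inversion of this model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import study_data as sd
from .phantom import PatientPhantom
from .volume import ImageVolume, quantize_hu

#: Reference tube current (mA) and BMI at which sigma_ref is defined.
REFERENCE_MA = 200.0
REFERENCE_BMI = 26.0
#: Default BMI sensitivity of noise, per kg/m^2 (free model parameter; the
#: study quantifies only that image quality degrades with BMI).
DEFAULT_BETA = 0.02
#: Tube-current clamp range, mA.
MA_RANGE = (10.0, 1000.0)


def _default_gains() -> dict[int, float]:
    gains = {120: 1.0}
    for kvp in (80, 70):
        gains[kvp] = (sd.ROI_NOISE_HU[kvp] / sd.ROI_NOISE_HU[120]) / math.sqrt(
            REFERENCE_MA / sd.TUBE_CURRENT_MA[kvp]
        )
    return gains


@dataclass(frozen=True)
class NoiseModel:
    """Parametric image-noise model (HU SD in a water-equivalent ROI)."""

    sigma_ref: float = sd.ROI_NOISE_HU[120]
    gains: dict[int, float] = field(default_factory=_default_gains)
    beta: float = DEFAULT_BETA

    def sd(self, kvp: int, tube_current: float, bmi: float) -> float:
        if kvp not in self.gains:
            raise ValueError(f"unsupported kvp {kvp}; supported: {sorted(self.gains)}")
        if tube_current <= 0:
            raise ValueError("tube_current must be positive")
        return (
            self.sigma_ref
            * self.gains[kvp]
            * math.sqrt(REFERENCE_MA / tube_current)
            * math.exp(self.beta * (bmi - REFERENCE_BMI))
        )


@dataclass(frozen=True)
class ScanProtocol:
    """One acquisition protocol: voltage, current, HU scaling, noise model."""

    kvp: int
    tube_current: float
    calcium_scale: float
    tissue_scale: float
    noise_model: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.kvp not in sd.SUPPORTED_KVP:
            raise ValueError(f"unsupported kvp {self.kvp}; supported: {list(sd.SUPPORTED_KVP)}")
        if self.tube_current <= 0:
            raise ValueError("tube_current must be positive")
        if self.kvp == 120 and not (self.calcium_scale == 1.0 and self.tissue_scale == 1.0):
            raise ValueError("at 120 kVp both HU scales must be 1 (reference protocol)")

    @classmethod
    def for_kvp(
        cls,
        kvp: int,
        tube_current: float | None = None,
        noise_model: NoiseModel | None = None,
    ) -> "ScanProtocol":
        """Study default for a voltage: the published scales and, unless
        overridden, the study's mean tube current."""
        if kvp not in sd.SUPPORTED_KVP:
            raise ValueError(f"unsupported kvp {kvp}; supported: {list(sd.SUPPORTED_KVP)}")
        return cls(
            kvp=kvp,
            tube_current=sd.TUBE_CURRENT_MA[kvp] if tube_current is None else tube_current,
            calcium_scale=sd.CALCIUM_SCALE[kvp],
            tissue_scale=sd.TISSUE_SCALE[kvp],
            noise_model=noise_model or NoiseModel(),
        )

    def with_tube_current(self, tube_current: float) -> "ScanProtocol":
        return replace(self, tube_current=tube_current)


def noise_sd(protocol: ScanProtocol, bmi: float) -> float:
    """Image noise (HU SD) for a protocol applied to a subject of given BMI."""
    if not (15.0 <= bmi <= 60.0):
        raise ValueError(f"bmi {bmi} outside the supported range [15, 60]")
    return protocol.noise_model.sd(protocol.kvp, protocol.tube_current, bmi)


def select_tube_current(
    kvp: int,
    bmi: float,
    target_noise: float,
    noise_model: NoiseModel | None = None,
) -> float:
    """Tube current (mA) that makes the modelled noise equal target_noise.

    Closed-form inversion of the noise model (the stand-in for the
    scanner's noise-index lookup), clamped to [10, 1000] mA with a warning
    when the target is unreachable.  The study's 120 kVp protocol bypasses
    this and fixes 200 mA.
    """
    if target_noise <= 0:
        raise ValueError("target_noise must be positive")
    model = noise_model or NoiseModel()
    base = model.sd(kvp, REFERENCE_MA, bmi)
    ma = REFERENCE_MA * (base / target_noise) ** 2
    lo, hi = MA_RANGE
    if ma < lo or ma > hi:
        clamped = min(max(ma, lo), hi)
        warnings.warn(
            f"target noise {target_noise:.1f} HU needs {ma:.0f} mA at {kvp} kVp; "
            f"clamped to {clamped:.0f} mA",
            RuntimeWarning,
            stacklevel=2,
        )
        return clamped
    return ma


def simulate_scan(
    phantom_volume: ImageVolume,
    ground_truth: PatientPhantom,
    protocol: ScanProtocol,
    seed: int | np.random.Generator,
) -> ImageVolume:
    """Simulate acquiring the phantom under a protocol.

    Calcium voxels (the ground-truth lesion pixels) are scaled by
    ``calcium_scale``, everything else by ``tissue_scale``; Gaussian noise
    with the modelled SD is added; HU are quantized to integers.  The same
    (volume, protocol, seed) always yields the same output.
    """
    if phantom_volume.shape != ground_truth.grid:
        raise ValueError(
            f"volume shape {phantom_volume.shape} does not match phantom grid {ground_truth.grid}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = phantom_volume.voxels * np.float64(protocol.tissue_scale)
    if protocol.calcium_scale != protocol.tissue_scale:
        for s, rows, cols in ground_truth.lesion_pixel_sets():
            out[s, rows, cols] = phantom_volume.voxels[s, rows, cols] * np.float64(protocol.calcium_scale)
    sigma = noise_sd(protocol, ground_truth.bmi)
    if sigma > 0:
        noise = rng.standard_normal(out.shape)
        noise *= sigma
        out += noise
    out += 0.5
    np.floor(out, out=out)
    return ImageVolume(
        out.astype(np.int16), phantom_volume.pixel_spacing, phantom_volume.slice_thickness
    )
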