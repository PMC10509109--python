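"""ROI signal/noise measurement and effective-dose estimation.

Signal and noise are read exactly as in the clinical protocol: a 20 mm
circular ROI in the aortic-root blood pool on one axial image, with the
mean HU as signal and the HU standard deviation as noise.  Effective dose
is the dose-length product (DLP) times a tube-voltage-dependent conversion
factor (0.0145 mSv/(mGy*cm) at 120 kVp, 0.0147 at 80 and 70 kVp).

The study does not print per-patient DLP; the simulator therefore attaches
a simple parametric DLP model (proportional to tube current, anchored at
the study's mean currents and mean doses) for its dose summaries.  Those
simulated doses are descriptive output, never a validation quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import study_data as sd
from .phantom import AORTIC_ROI_DIAMETER_MM, disc_pixels
from .volume import ImageVolume


@dataclass(frozen=True)
class RoiStats:
    """Mean (signal), SD (noise) and their ratio inside a circular ROI."""

    signal: float
    noise: float
    snr: float | None  # None when noise is zero (constant region)
    n_pixels: int


def roi_stats(
    volume: ImageVolume,
    center: tuple[int, float, float],
    diameter: float = AORTIC_ROI_DIAMETER_MM,
) -> RoiStats:
    """Signal/noise statistics in a circular single-slice ROI.

    ``center`` is (slice, row, col); ``diameter`` in mm.  The ROI covers
    pixels whose centers lie within diameter/2 of the center and must fit
    inside the grid.
    """
    s, r, c = center
    if not (0 <= s < volume.n_slices):
        raise ValueError(f"ROI slice {s} outside the volume ({volume.n_slices} slices)")
    rows, cols = disc_pixels((r, c), diameter / 2.0, volume.pixel_spacing, volume.shape[1:])
    values = volume.voxels[s, rows, cols].astype(float)
    signal = float(values.mean())
    noise = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RoiStats(
        signal=signal,
        noise=noise,
        snr=signal / noise if noise > 0 else None,
        n_pixels=values.size,
    )


def effective_dose(dlp: float, kvp: int) -> float:
    """Effective dose (mSv) from a dose-length product (mGy*cm)."""
    if dlp < 0:
        raise ValueError("dlp must be non-negative")
    if kvp not in sd.DOSE_CONVERSION:
        raise ValueError(f"unsupported kvp {kvp}; supported: {sorted(sd.DOSE_CONVERSION)}")
    return dlp * sd.DOSE_CONVERSION[kvp]


#: Reference DLP (mGy*cm) per voltage at the study's mean tube currents,
#: back-computed from the study's mean effective doses.
DLP_REFERENCE = {
    kvp: sd.MEAN_EFFECTIVE_DOSE_MSV[kvp] / sd.DOSE_CONVERSION[kvp] for kvp in sd.SUPPORTED_KVP
}


def dlp_model(kvp: int, tube_current: float) -> float:
    """Parametric DLP (mGy*cm): linear in tube current at fixed voltage,
    anchored at the study's mean current for that voltage."""
    if kvp not in DLP_REFERENCE:
        raise ValueError(f"unsupported kvp {kvp}; supported: {sorted(DLP_REFERENCE)}")
    if tube_current <= 0:
        raise ValueError("tube_current must be positive")
    return DLP_REFERENCE[kvp] * tube_current / sd.TUBE_CURRENT_MA[kvp]
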