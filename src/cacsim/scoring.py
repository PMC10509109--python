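"""Agatston-type coronary calcium scoring with voltage-adapted thresholds.

Per axial slice, pixels at or above the lowest density threshold are grouped
into 8-connected components; components covering at least 1 mm^2 count as
lesions (this minimum-area rule is what suppresses isolated noise pixels).
Each lesion scores (density weight 1-4, from its peak HU against the
threshold table) x (area in mm^2); the total CAC score is the sum over all
slices.  Risk classes follow the usual ordinal bands 0, 1-10, 11-100,
101-400, >400 on the half-up-rounded total.

At 120 kVp the thresholds are the classic 130/200/300/400 HU; at 80 and
70 kVp the adapted tables (177/272/409/545 and 207/319/478/637) compensate
for the increased calcium attenuation at lower photon energy.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .study_data import RISK_CLASS_LABELS, SUPPORTED_KVP, THRESHOLD_BOUNDS
from .volume import ImageVolume

#: Minimum lesion area, mm^2.
MIN_LESION_AREA_MM2 = 1.0

#: 8-connectivity structure for in-plane component labelling.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdTable:
    """Density-score lower bounds (t1..t4, HU) for one tube voltage.

    A peak of t1..t2-1 HU scores weight 1, ..., >= t4 scores weight 4
    (inclusive integer lower bounds).
    """

    kvp: int
    bounds: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        t1, t2, t3, t4 = self.bounds
        if not (t1 < t2 < t3 < t4):
            raise ValueError(f"threshold bounds must be strictly increasing, got {self.bounds}")

    @property
    def t1(self) -> int:
        return self.bounds[0]


def threshold_table(kvp: int) -> ThresholdTable:
    """The published threshold table for a supported tube voltage."""
    if kvp not in THRESHOLD_BOUNDS:
        raise ValueError(f"unsupported kvp {kvp}; supported: {sorted(SUPPORTED_KVP)}")
    return ThresholdTable(kvp=kvp, bounds=THRESHOLD_BOUNDS[kvp])


def density_weight(peak_hu: float, table: ThresholdTable) -> int:
    """Agatston density weight (0-4) of a lesion peak attenuation.

    0 means below the detection threshold t1.
    """
    return int(np.searchsorted(table.bounds, peak_hu, side="right"))


class RiskClass(enum.IntEnum):
    """Ordinal cardiovascular risk class from the total CAC score."""

    ZERO = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return RISK_CLASS_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "RiskClass":
        try:
            return cls(RISK_CLASS_LABELS.index(label))
        except ValueError:
            raise ValueError(
                f"unknown risk class {label!r}; expected one of {RISK_CLASS_LABELS}"
            ) from None


@dataclass
class DetectedLesion:
    """One suprathreshold 8-connected in-plane component of area >= 1 mm^2."""

    slice_index: int
    pixel_set: np.ndarray  # (k, 2) array of (row, col) indices
    area: float  # mm^2
    peak_hu: int
    density_weight: int
    lesion_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.lesion_score = self.density_weight * self.area


@dataclass
class CacResult:
    """Total Agatston-type score, its risk class, and the audit lesion list."""

    total_score: float
    rounded_score: int
    risk_class: RiskClass
    lesions: list[DetectedLesion]
    kvp: int


def detect_lesions(
    volume: ImageVolume,
    table: ThresholdTable,
    min_area: float = MIN_LESION_AREA_MM2,
    keep_pixel_sets: bool = True,
) -> list[DetectedLesion]:
    """Find calcified lesions slice by slice.

    Pixels with HU >= t1 are grouped into 8-connected in-plane components;
    components with pixel_count x pixel_area >= ``min_area`` become
    lesions, with the component's maximum HU as peak.  ``keep_pixel_sets``
    can be disabled to skip materializing per-lesion pixel coordinates in
    large simulation sweeps.
    """
    if volume.pixel_spacing is None or not volume.pixel_spacing > 0:
        raise ValueError("volume has no valid pixel spacing")
    px_area = volume.pixel_area
    min_pixels = math.ceil(min_area / px_area - 1e-9)
    lesions: list[DetectedLesion] = []
    for s in range(volume.n_slices):
        sl = volume.voxels[s]
        mask = sl >= table.t1
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(counts >= min_pixels) + 1
        if keep.size == 0:
            continue
        boxes = ndimage.find_objects(labels)
        for lab in keep:
            box = boxes[lab - 1]
            sel = labels[box] == lab
            peak = int(sl[box][sel].max())
            if keep_pixel_sets:
                pixel_set = np.argwhere(sel)
                pixel_set[:, 0] += box[0].start
                pixel_set[:, 1] += box[1].start
            else:
                pixel_set = np.empty((0, 2), dtype=int)
            lesions.append(
                DetectedLesion(
                    slice_index=s,
                    pixel_set=pixel_set,
                    area=counts[lab - 1] * px_area,
                    peak_hu=peak,
                    density_weight=density_weight(peak, table),
                )
            )
    return lesions


def agatston_score(lesions: list[DetectedLesion]) -> float:
    """Total score: sum of density_weight x area over all lesions."""
    return float(sum(l.lesion_score for l in lesions))


def risk_class(total_score: float) -> RiskClass:
    """Risk class of a total CAC score (half-up rounding to integer)."""
    if total_score < 0:
        raise ValueError("total_score must be non-negative")
    s = math.floor(total_score + 0.5)
    if s == 0:
        return RiskClass.ZERO
    if s <= 10:
        return RiskClass.LOW
    if s <= 100:
        return RiskClass.MODERATE
    if s <= 400:
        return RiskClass.HIGH
    return RiskClass.VERY_HIGH


def score_volume(
    volume: ImageVolume,
    kvp: int,
    min_area: float = MIN_LESION_AREA_MM2,
    keep_pixel_sets: bool = True,
) -> CacResult:
    """Detect lesions with the voltage's threshold table and score them."""
    table = threshold_table(kvp)
    lesions = detect_lesions(volume, table, min_area=min_area, keep_pixel_sets=keep_pixel_sets)
    total = agatston_score(lesions)
    return CacResult(
        total_score=total,
        rounded_score=math.floor(total + 0.5),
        risk_class=risk_class(total),
        lesions=lesions,
        kvp=kvp,
    )
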