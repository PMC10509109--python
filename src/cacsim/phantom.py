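"""Digital cardiac phantoms for CAC-scoring simulation.

A :class:`PatientPhantom` is the ground truth for one synthetic subject: a
set of calcific disc lesions (position, area, peak attenuation at the
120 kVp reference), an aortic-root blood pool for signal/noise measurement,
the subject's BMI, and the reconstruction geometry.  :func:`build_phantom`
rasterizes it into the noiseless 120 kVp reference volume.

Design choices: lesions are uniform discs (every pixel at the peak HU), so
ground-truth Agatston density weights are exact; overlapping lesions are
rejected rather than merged, keeping per-lesion ground truth unambiguous.
No beam hardening, scatter, partial volume or motion is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import (
    DEFAULT_MATRIX,
    DEFAULT_PIXEL_SPACING_MM,
    DEFAULT_SLICE_THICKNESS_MM,
    ImageVolume,
    quantize_hu,
)

#: Uniform soft-tissue background of the phantom, HU at 120 kVp.
SOFT_TISSUE_HU = 40.0
#: Radius of the aortic blood-pool cylinder, mm (aortic root ~30 mm across,
#: comfortably containing the 20 mm measurement ROI).
BLOOD_POOL_RADIUS_MM = 15.0
#: Default blood-pool attenuation at 120 kVp, HU.
DEFAULT_BLOOD_POOL_HU = 48.5
#: Diameter of the aortic measurement ROI, mm.
AORTIC_ROI_DIAMETER_MM = 20.0


class PhantomSpecError(ValueError):
    """An invalid phantom specification (lesion out of grid, overlap, ...)."""


def disc_pixels(
    center: tuple[float, float],
    radius_mm: float,
    pixel_spacing: float,
    grid_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices whose centers fall within a disc.

    ``center`` is in (row, col) pixel coordinates; ``radius_mm`` in mm.
    Returns index arrays; when ``grid_shape`` is given, indices outside the
    grid raise :class:`PhantomSpecError`.
    """
    r_px = radius_mm / pixel_spacing
    r0, c0 = center
    lo_r = math.floor(r0 - r_px) - 1
    hi_r = math.ceil(r0 + r_px) + 1
    lo_c = math.floor(c0 - r_px) - 1
    hi_c = math.ceil(c0 + r_px) + 1
    rr, cc = np.meshgrid(np.arange(lo_r, hi_r + 1), np.arange(lo_c, hi_c + 1), indexing="ij")
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= r_px**2
    rows, cols = rr[inside], cc[inside]
    if grid_shape is not None:
        if rows.size and (
            rows.min() < 0 or cols.min() < 0 or rows.max() >= grid_shape[0] or cols.max() >= grid_shape[1]
        ):
            raise PhantomSpecError("disc extends outside the image grid")
    return rows, cols


@dataclass
class LesionSpec:
    """One calcific lesion: a uniform disc on a single slice.

    Parameters
    ----------
    slice_index : axial slice holding the lesion
    center : (row, col) pixel coordinates of the disc center
    target_area : requested disc area, mm^2 (the rasterized area is the
        closest achievable on the pixel grid and is reported back in
        ``rasterized_area`` after :func:`build_phantom`)
    peak_hu_ref : lesion attenuation at the 120 kVp reference, HU
    """

    slice_index: int
    center: tuple[float, float]
    target_area: float
    peak_hu_ref: float
    shape: str = "disc"
    rasterized_area: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.shape != "disc":
            raise PhantomSpecError(f"unsupported lesion shape {self.shape!r}; only 'disc'")
        if not self.target_area > 0:
            raise PhantomSpecError("target_area must be positive")
        if self.peak_hu_ref < 0:
            raise PhantomSpecError("peak_hu_ref must be non-negative")

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.target_area / math.pi)

    def pixels(self, pixel_spacing: float, grid_shape: tuple[int, int] | None = None):
        """Rasterize the disc; see :func:`disc_pixels`."""
        return disc_pixels(self.center, self.radius_mm, pixel_spacing, grid_shape)


@dataclass
class PatientPhantom:
    """Ground truth for one synthetic subject."""

    lesions: list[LesionSpec] = field(default_factory=list)
    bmi: float = 26.0
    aortic_roi_center: tuple[int, int, int] = (0, DEFAULT_MATRIX // 2, DEFAULT_MATRIX // 2)
    blood_pool_hu_ref: float = DEFAULT_BLOOD_POOL_HU
    grid: tuple[int, int, int] = (4, DEFAULT_MATRIX, DEFAULT_MATRIX)
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_MM

    def __post_init__(self) -> None:
        if not (15.0 <= self.bmi <= 60.0):
            raise PhantomSpecError(f"bmi {self.bmi} outside the supported range [15, 60]")
        if not self.pixel_spacing > 0:
            raise PhantomSpecError("pixel_spacing must be positive")
        s, r, c = self.aortic_roi_center
        roi_r_px = (AORTIC_ROI_DIAMETER_MM / 2) / self.pixel_spacing
        if not (0 <= s < self.grid[0]):
            raise PhantomSpecError("aortic ROI slice outside the grid")
        if (
            r - roi_r_px < 0
            or c - roi_r_px < 0
            or r + roi_r_px >= self.grid[1]
            or c + roi_r_px >= self.grid[2]
        ):
            raise PhantomSpecError("the 20 mm aortic ROI does not fit inside the grid")

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing**2

    def lesion_pixel_sets(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """Rasterize every lesion: list of (slice_index, rows, cols)."""
        out = []
        for i, les in enumerate(self.lesions):
            if not (0 <= les.slice_index < self.grid[0]):
                raise PhantomSpecError(f"lesion {i} on slice {les.slice_index} outside the grid")
            try:
                rows, cols = les.pixels(self.pixel_spacing, self.grid[1:])
            except PhantomSpecError as exc:
                raise PhantomSpecError(f"lesion {i}: {exc}") from exc
            out.append((les.slice_index, rows, cols))
        return out

    def calcium_mask(self) -> np.ndarray:
        """Boolean voxel mask of all lesion pixels."""
        mask = np.zeros(self.grid, dtype=bool)
        for s, rows, cols in self.lesion_pixel_sets():
            mask[s, rows, cols] = True
        return mask

    def noiseless_score(self) -> float:
        """Ground-truth 120 kVp Agatston score from the rasterized lesions.

        Uniform discs make this exact: each lesion contributes
        (density weight of its peak) x (pixel count x pixel area), provided
        it meets the 1 mm^2 minimum-area rule.
        """
        from .scoring import density_weight, threshold_table

        table = threshold_table(120)
        total = 0.0
        for (s, rows, cols), les in zip(self.lesion_pixel_sets(), self.lesions):
            area = rows.size * self.pixel_area
            if area < 1.0:
                continue
            w = density_weight(int(np.floor(les.peak_hu_ref + 0.5)), table)
            total += w * area
        return total


def build_phantom(spec: PatientPhantom) -> ImageVolume:
    """Rasterize a phantom into its noiseless 120 kVp reference volume.

    Background soft tissue at 40 HU, a blood-pool cylinder (through all
    slices) at ``blood_pool_hu_ref`` around the aortic ROI position, and
    each lesion's pixels at its ``peak_hu_ref``.  Each lesion's achieved
    (rasterized) area is written back onto its spec.

    Raises
    ------
    PhantomSpecError
        If a lesion leaves the grid, overlaps another lesion, or intrudes
        into the blood-pool cylinder (which would contaminate the noise ROI).
    """
    vol = np.full(spec.grid, SOFT_TISSUE_HU, dtype=np.float64)

    _, ar, ac = spec.aortic_roi_center
    pool_rows, pool_cols = disc_pixels((ar, ac), BLOOD_POOL_RADIUS_MM, spec.pixel_spacing, spec.grid[1:])
    vol[:, pool_rows, pool_cols] = spec.blood_pool_hu_ref
    pool_set = set(zip(pool_rows.tolist(), pool_cols.tolist()))

    occupied: dict[int, set[tuple[int, int]]] = {}
    for i, ((s, rows, cols), les) in enumerate(zip(spec.lesion_pixel_sets(), spec.lesions)):
        px = set(zip(rows.tolist(), cols.tolist()))
        if not px:
            raise PhantomSpecError(f"lesion {i} rasterizes to zero pixels (target_area too small)")
        if px & pool_set:
            raise PhantomSpecError(f"lesion {i} overlaps the aortic blood pool")
        taken = occupied.setdefault(s, set())
        if px & taken:
            raise PhantomSpecError(f"lesion {i} overlaps another lesion on slice {s}")
        taken |= px
        vol[s, rows, cols] = les.peak_hu_ref
        les.rasterized_area = rows.size * spec.pixel_area

    return ImageVolume(quantize_hu(vol), spec.pixel_spacing, spec.slice_thickness)
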