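"""3D CT-like attenuation volumes.

An :class:`ImageVolume` is a stack of axial slices of integer Hounsfield
units with in-plane pixel spacing and slice thickness, matching a
non-contrast cardiac CT reconstruction (default: 25 cm displayed field of
view on a 512x512 matrix, 2.5 mm slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: 25 cm displayed field of view across a 512-pixel matrix.
DEFAULT_PIXEL_SPACING_MM = 250.0 / 512.0  # 0.48828125
DEFAULT_SLICE_THICKNESS_MM = 2.5
DEFAULT_MATRIX = 512


def quantize_hu(values: np.ndarray) -> np.ndarray:
    """Round attenuation values to integer HU, half away from zero upward.

    CT numbers are stored as integers; half-up rounding keeps the adapted
    thresholds exactly consistent with the 120 kVp ones at the published
    boundaries (e.g. 200 HU x 1.5925 = 318.5 -> 319, the 70 kVp bound).
    """
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int16, copy=False)
    # float64 throughout: scale products such as 200 * 1.5925 = 318.5 must
    # hit the .5 boundary exactly before the half-up shift
    out = arr.astype(np.float64, copy=True)
    out += 0.5
    np.floor(out, out=out)
    return out.astype(np.int16)


@dataclass
class ImageVolume:
    """A 3D grid of integer attenuation values (HU) with geometry metadata.

    Attributes
    ----------
    voxels : (n_slices, n_rows, n_cols) int array, HU
    pixel_spacing : in-plane pixel size, mm
    slice_thickness : slice increment, mm
    """

    voxels: np.ndarray
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_MM

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slices, rows, cols), got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must hold integer HU values; quantize first (quantize_hu)")
        if not (self.pixel_spacing > 0 and self.slice_thickness > 0):
            raise ValueError("pixel_spacing and slice_thickness must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel, mm^2."""
        return self.pixel_spacing**2

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.pixel_spacing, self.slice_thickness)

    # --- standard-format I/O -------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write the volume as a single-file NIfTI image (.nii/.nii.gz).

        Axis order is converted to (x=cols, y=rows, z=slices) with the
        spacing metadata in the affine, so third-party viewers display the
        phantom with correct geometry.
        """
        import nibabel as nib

        data = np.transpose(self.voxels, (2, 1, 0)).astype(np.int16)
        affine = np.diag([self.pixel_spacing, self.pixel_spacing, self.slice_thickness, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        """Read a volume written by :meth:`to_nifti` (or any NIfTI volume
        holding integer HU with isotropic in-plane spacing)."""
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if abs(zooms[0] - zooms[1]) > 1e-6:
            raise ValueError("anisotropic in-plane spacing is not supported")
        data = np.asanyarray(img.dataobj)
        voxels = np.transpose(data, (2, 1, 0))
        return cls(quantize_hu(voxels), float(zooms[0]), float(zooms[2]))
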