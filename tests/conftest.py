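import numpy as np
import pytest

from cacsim import ImageVolume, LesionSpec, PatientPhantom, build_phantom

MATRIX = 512
SPACING = 250.0 / 512.0
PIXEL_AREA = SPACING**2


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def simple_phantom():
    """One 4 mm^2 / 320 HU lesion plus the aortic blood pool."""
    return PatientPhantom(
        lesions=[LesionSpec(slice_index=1, center=(150.0, 150.0), target_area=4.0, peak_hu_ref=320.0)],
        bmi=26.0,
        grid=(3, MATRIX, MATRIX),
    )


@pytest.fixture
def simple_volume(simple_phantom):
    return build_phantom(simple_phantom)


def make_volume(voxels, spacing=SPACING):
    """Small helper: wrap an integer array as an ImageVolume."""
    return ImageVolume(np.asarray(voxels, dtype=np.int16), pixel_spacing=spacing)
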