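import dataclasses

import numpy as np
import pytest

from isfc import synthetic_data as sd
from isfc.roi_sampling import ROIDef, ROILayout
from isfc.volume import AnimalVolume


@pytest.fixture(scope="session")
def default_cohort():
    """Standard two-group cohort spec + 74-ROI layout (session-cached)."""
    return sd.default_cohort(seed=0)


@pytest.fixture()
def small_layout():
    """Five-slice, two-band layout on a small volume grid."""
    rois = []
    for band, k in (("dorsal", 30), ("ventral", 10)):
        for idx in range(5):
            rois.append(
                ROIDef(
                    name=f"{band[0].upper()}{idx + 1}",
                    band=band,
                    hemisphere="right",
                    bregma_mm=2.56 - 0.14 * idx,
                    center=(16, 3 + idx, k),
                    diameter_um=100.0,
                )
            )
    return ROILayout(rois, spacing_mm=0.14)


@pytest.fixture()
def small_shape():
    return (32, 12, 40)


def make_volume(data, animal_id="a1", group="g", voxel=(40.0, 140.0, 40.0)):
    return AnimalVolume(animal_id=animal_id, group=group, data=np.asarray(data, dtype=float), voxel_size_um=voxel)


@pytest.fixture()
def constant_volume(small_shape):
    return make_volume(np.full(small_shape, 2.0))


def pairwise_r(values):
    """Plain pairwise Pearson r used as an independent check in tests."""
    return np.corrcoef(np.asarray(values, dtype=float), rowvar=False)
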