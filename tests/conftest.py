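import numpy as np
import pytest

from dynconn.rois import default_roi_set
from dynconn.synthgen import GeneratorConfig, RoiTimeSeries


@pytest.fixture(scope="session")
def roi_set():
    return default_roi_set()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_voxel_config():
    """8x8x4 lattice that fits the full layout (20 regions x 4 voxels + WM/CSF)."""
    return GeneratorConfig(
        seed=123,
        n_subjects_per_group=2,
        T_volumes=200,
        groups=("awake",),
        lattice_shape=(8, 8, 4),
        voxels_per_region=4,
        n_wm_voxels=12,
        n_csf_voxels=12,
    )


def make_series(data, roi_set, subject_id="s1", condition="awake"):
    return RoiTimeSeries(
        data=np.asarray(data, float),
        roi_set=roi_set,
        subject_id=subject_id,
        condition=condition,
    )
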