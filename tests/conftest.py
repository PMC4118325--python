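import pytest

from stemsense import (
    RigConfig,
    RoiFilter,
    StemDetectionParams,
    filter_roi,
    generate_field,
    noise_free_config,
    scans_to_points,
)


@pytest.fixture(scope="session")
def rig():
    return RigConfig()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic 20-tree row, all alive, no nuisance objects."""
    return generate_field(noise_free_config(seed=42))


@pytest.fixture(scope="session")
def noise_free_roi_cloud(noise_free_dataset, rig):
    cloud = scans_to_points(noise_free_dataset.scans, rig)
    return filter_roi(cloud, RoiFilter(), rig)


@pytest.fixture(scope="session")
def default_params():
    return StemDetectionParams()
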