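import numpy as np
import pytest

from octaqa import (
    CohortSpec,
    ImageCalibration,
    SceneConfig,
    build_etdrs_grid,
    generate_angiogram,
    generate_cohort_metrics,
)
from octaqa.etdrs_grid import PIXEL_SIZE_3MM_245


@pytest.fixture(scope="session")
def calib245():
    return ImageCalibration(245, 245, PIXEL_SIZE_3MM_245, (122.0, 122.0), "OD")


@pytest.fixture(scope="session")
def grid245(calib245):
    return build_etdrs_grid(calib245)


@pytest.fixture(scope="session")
def default_cohort():
    """One metric-level cohort at the default 27/21/10 study sizes."""
    return generate_cohort_metrics(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def scene128():
    """Small image-level scene for pipeline tests (desk-scale raster)."""
    return generate_angiogram(SceneConfig(size_px=128), seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
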