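import numpy as np
import pytest
from shapely.geometry import box

from coralspat.survey import SurveyDataset, TransectRecord


@pytest.fixture
def small_survey() -> SurveyDataset:
    """Five transects in a 1 km square with known counts."""
    records = [
        TransectRecord("a", 100.0, 100.0, 4, 1, depth=5.0),
        TransectRecord("b", 200.0, 100.0, 6, 0, depth=7.0),
        TransectRecord("c", 500.0, 500.0, 2, 0),
        TransectRecord("d", 800.0, 300.0, 10, 3, depth=9.0),
        TransectRecord("e", 900.0, 900.0, 1, 0),
    ]
    return SurveyDataset.from_records(records, region=box(0, 0, 1000, 1000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
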