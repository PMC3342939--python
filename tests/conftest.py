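import sys
from datetime import datetime, time
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from flysleep.dam import ActivitySeries

START = datetime(2012, 1, 2, 8, 0)  # series start at lights-on (ZT0)


def make_series(counts, fly_id="fly00", regime="LD12:12", start=START, lights_on=time(8, 0)):
    return ActivitySeries(
        fly_id=fly_id,
        start_time=start,
        counts=np.asarray(counts, dtype=float),
        regime=regime,
        lights_on=lights_on,
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
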