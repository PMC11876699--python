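import logging

import numpy as np
import pytest

from tirfquant.images import ImagingParams, NoiseModel


@pytest.fixture(autouse=True)
def _quiet_dropped_event_warnings():
    logging.getLogger("tirfquant.kymo").setLevel(logging.ERROR)
    yield


@pytest.fixture
def imaging_noiseless() -> ImagingParams:
    return ImagingParams(noise=NoiseModel(kind="none"))


@pytest.fixture
def imaging_default() -> ImagingParams:
    return ImagingParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
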