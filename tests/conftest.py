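import numpy as np
import pytest

from aisquant.synthetic import AISGroundTruth, SpikeModelParams


@pytest.fixture
def default_spike_params():
    return SpikeModelParams(rheobase_pA=145.0)


@pytest.fixture
def sharp_truth():
    """Unblurred, noiseless plateau on [5, 25] um."""
    return AISGroundTruth(start_um=5.0, end_um=25.0)


@pytest.fixture
def blurred_truth():
    return AISGroundTruth(start_um=5.0, end_um=25.0, psf_sigma_um=0.5)
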