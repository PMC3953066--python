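import numpy as np
import pytest

from seednmr.core import AcquisitionConfig, NoiseModel, simulate_decay
from seednmr.reference import reference_set


def joint_curves(component_set, noise_sd=0.0, seed=0):
    """Simulate the standard joint acquisition: default FID + CPMG."""
    fid = simulate_decay(component_set, AcquisitionConfig.fid(),
                         NoiseModel(noise_sd, seed))
    cpmg = simulate_decay(component_set, AcquisitionConfig.cpmg(),
                          NoiseModel(noise_sd, seed + 1))
    return [fid, cpmg]


@pytest.fixture
def wt_dry():
    return reference_set("wt-dry")


@pytest.fixture
def wt_imb():
    return reference_set("wt-imb-24h")


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="MEM optimizer stopped early")
        yield
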