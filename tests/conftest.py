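import numpy as np
import pytest

from defolmap.synthetic_scene import make_fixture

#: published reference coefficients (intercept a, slope b) of the logistic
#: calibration for each index-change predictor, and the threshold limits and
#: confusion matrix they go with; used as inputs to reproduction tests.
REFERENCE_COEFS = {
    "dMID": (-3.1299111, -0.0041928),
    "dMSI": (-3.3570352, -0.0092755),
    "dNDMI": (-3.5552389, 0.0014107),
    "dNDVI": (-3.509468, 0.001767),
    "dNBR": (-3.6323329, -0.0013874),
}

REFERENCE_R2 = {"dMID": 0.740, "dMSI": 0.815, "dNDMI": 0.749, "dNDVI": 0.787, "dNBR": 0.776}

REFERENCE_LIMITS = {
    "dMID": (-222, -599, -949),
    "dMSI": (-125, -295, -453),
    "dNDMI": (963, 2081, 3121),
    "dNDVI": (743, 1636, 2466),
    "dNBR": (1034, 2172, 3229),  # printed positive; the printed slope is negative
}

REFERENCE_CONFUSION = np.array(
    [
        [9, 1, 0, 0],
        [2, 17, 4, 0],
        [0, 3, 4, 1],
        [0, 0, 3, 6],
    ]
)

REFERENCE_QUOTAS = {"nil": 10, "low": 23, "medium": 8, "high": 9}


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def default_fixture():
    return make_fixture("default", seed=0)
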