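import numpy as np
import pytest

from revphi import DetectorConfig


def sign_floor(values, frac=0.05):
    """Noise floor for sign classification: a fraction of the largest
    absolute value (onset transients and discretization leave opposite-sign
    residue of a few percent of the peak)."""
    return frac * np.abs(np.asarray(values)).max()


@pytest.fixture(scope="session")
def cfg_2q():
    return DetectorConfig(model="2Q")


@pytest.fixture(scope="session")
def cfg_4q():
    return DetectorConfig(model="4Q", dc_frac_on=0.0, dc_frac_off=0.0)


@pytest.fixture(scope="session")
def small_cfg_2q():
    """Short array for fast unit tests."""
    return DetectorConfig(model="2Q", n_detectors=12)


@pytest.fixture(scope="session")
def small_cfg_4q():
    return DetectorConfig(model="4Q", n_detectors=12, dc_frac_on=0.0, dc_frac_off=0.0)
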