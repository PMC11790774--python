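import numpy as np
import pytest

import cardiodti as cd


@pytest.fixture(scope="session")
def default_spec():
    return cd.PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantom(default_spec):
    """Default healthy-LV phantom without noise (shared, read-only)."""
    return cd.make_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_phantom):
    ds = noiseless_phantom
    return cd.DiffusionTensorModel(ds.dwi_clean, ds.gtab, ds.mask).fit()


@pytest.fixture(scope="session")
def snr50_phantom():
    return cd.make_phantom(cd.PhantomSpec(snr=50.0, seed=1))


@pytest.fixture(scope="session")
def gtab15():
    return cd.make_gradient_table(3, 12, 1123.0)


def angular_error_deg(ha, ha_true):
    """Absolute HA difference folded onto [0, 90] (axial quantity)."""
    err = np.abs(ha - ha_true)
    return np.where(err > 90.0, 180.0 - err, err)
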