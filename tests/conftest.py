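import numpy as np
import pytest

from fcivim.design import reference_scheme_50
from fcivim.hardware import DEFAULT_HARDWARE
from fcivim.model import AcquisitionPoint, AcquisitionScheme, TissueParams, forward_signal
from fcivim.phase import default_tables


@pytest.fixture(scope="session")
def hw():
    return DEFAULT_HARDWARE


@pytest.fixture(scope="session")
def tables():
    """Cached attenuation tables shared by the whole suite."""
    return default_tables()


@pytest.fixture(scope="session")
def rich_scheme():
    """Two-shape, three-T scheme with good coverage for recovery tests."""
    pts = []
    for T in (40.0, 70.0, 100.0):
        for b in (0, 10, 20, 40, 80, 150, 300, 500):
            pts.append(AcquisitionPoint(float(b), T, 0))
    fc_max = {40.0: 180, 70.0: 1000, 100.0: 2900}
    for T in (40.0, 70.0, 100.0):
        for b in (0, 10, 30, 60, 100, 150):
            if b <= fc_max[T]:
                pts.append(AcquisitionPoint(float(b), T, 1))
    return AcquisitionScheme(pts, label="rich")


@pytest.fixture(scope="session")
def opt50():
    return reference_scheme_50()


@pytest.fixture(scope="session")
def interior_truth():
    return TissueParams(D=1.5e-3, f=0.25, tau=150.0, v=5.0)


@pytest.fixture(scope="session")
def noiseless_curve(rich_scheme, interior_truth, tables):
    return forward_signal(rich_scheme, interior_truth, tables=tables)
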