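import numpy as np
import pytest

from inclination.biomarkers import default_panel, panel_by_name


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def specs(panel):
    return panel_by_name(panel)


@pytest.fixture(scope="session")
def sbp(specs):
    return specs["sBP"]


@pytest.fixture(scope="session")
def hdl(specs):
    return specs["HDL"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
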