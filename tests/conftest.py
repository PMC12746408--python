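import pytest

from phantomgel import default_calibration, tissue_targets


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def targets():
    return tissue_targets()
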