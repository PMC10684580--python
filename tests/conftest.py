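import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mcshape import AcquisitionSettings, regime_presets


@pytest.fixture(scope="session")
def presets():
    """The two published simulation parameter sets (noiseless templates)."""
    return regime_presets()


@pytest.fixture(scope="session")
def acq_fast():
    """Small acquisition for speed-sensitive fitting tests."""
    return AcquisitionSettings(n_points=1024)


@pytest.fixture(scope="session")
def acq_fine():
    """High-resolution, unapodized acquisition for line-width metrology."""
    return AcquisitionSettings(apodization="none", n_points=4096, zero_fill_factor=4)
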