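import numpy as np
import pytest

from acinusfsi.geometry import build_geometry
from acinusfsi.materials import MaterialNeoHookean


@pytest.fixture(scope="session")
def tissue():
    """Tabulated acinar tissue: E = 35,714 Pa, nu = 0.42."""
    return MaterialNeoHookean(E=35714.0, nu=0.42)


@pytest.fixture(scope="session")
def healthy_geom():
    """Calibrated healthy acinus at the coarse shell level (fast tests)."""
    return build_geometry("healthy", envelope_level=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
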