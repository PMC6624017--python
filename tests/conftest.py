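import numpy as np
import pytest

from gradientscape.model import ChamberGeometry, GrowthKinetics, UptakeKinetics
from gradientscape.synth import SyntheticScenario


@pytest.fixture(scope="session")
def geometry():
    return ChamberGeometry()


@pytest.fixture(scope="session")
def scenario_clean():
    """Noiseless, perdurance-free default 2% scenario (exact closed loops)."""
    return SyntheticScenario(seed=3, noise_cv=0.0, perdurance_um=0.0)


@pytest.fixture(scope="session")
def scenario_default():
    """Default 2% scenario with noise and perdurance."""
    return SyntheticScenario(seed=5)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clamped")
        yield
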